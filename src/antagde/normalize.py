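"""Quantile normalization, probe-set collapsing, and expressed-gene calling."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DetectionCalls, ExpressionMatrix, ValidationError


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    Each column is replaced by the across-sample mean of sorted values at its
    ranks; tied values within a column share the mean of the reference values
    at their tied ranks.  Normalization is joint across all samples of all
    genotypes, so cross-genotype fold changes are on one scale.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs ≥2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    n = vals.shape[0]
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        sorter = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[sorter] = reference
        # ties share the mean reference value across their tied ranks
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return matrix.with_values(out)


def collapse_probesets_mean(matrix: ExpressionMatrix, mapping: pd.Series) -> ExpressionMatrix:
    """Collapse probe sets to genes by the per-sample arithmetic mean.

    ``mapping`` is probe-set id → gene id and must cover every matrix row;
    a probe set mapped to more than one gene is an error.
    """
    missing = matrix.values.index.difference(mapping.index)
    if len(missing):
        raise ValidationError(f"probe sets without gene mapping: {missing[:5].tolist()}")
    if mapping.index.has_duplicates:
        dups = mapping.index[mapping.index.duplicated()][:5].tolist()
        raise ValidationError(f"probe sets mapped to multiple genes: {dups}")
    genes = mapping.loc[matrix.values.index]
    collapsed = matrix.values.groupby(genes.to_numpy()).mean()
    collapsed.index.name = matrix.values.index.name
    gene_meta = matrix.genes.groupby(genes.to_numpy()).first()
    gene_meta = gene_meta.loc[collapsed.index]
    return ExpressionMatrix(collapsed, matrix.samples, gene_meta)


def collapse_probesets_best(contrast_table: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Per gene, keep the probe set with the strongest significance.

    Ranked by smallest q, then smallest p, then lexicographic probe-set id.
    ``contrast_table`` must carry ``gene`` (probe-set id), ``p`` and ``q``
    columns; the returned table has one row per gene with the winning probe
    set recorded in ``probe_set``.
    """
    missing = set(contrast_table["gene"]) - set(mapping.index)
    if missing:
        raise ValidationError(f"probe sets without gene mapping: {sorted(missing)[:5]}")
    tab = contrast_table.copy()
    tab["probe_set"] = tab["gene"]
    tab["gene"] = mapping.loc[tab["probe_set"]].to_numpy()
    tab = tab.sort_values(["q", "p", "probe_set"], kind="mergesort")
    best = tab.drop_duplicates("gene", keep="first")
    return best.sort_values("gene", kind="mergesort").reset_index(drop=True)


def call_expressed(calls: DetectionCalls) -> pd.Series:
    """Expressed ⇔ ≥2 Present calls, or ≥1 Present and ≥1 Marginal.

    The rule is applied across the replicate columns passed in (restrict the
    calls to one genotype's replicates first, e.g. WT).
    """
    labels = calls.labels.to_numpy()
    n_present = (labels == "P").sum(axis=1)
    n_marginal = (labels == "M").sum(axis=1)
    expressed = (n_present >= 2) | ((n_present >= 1) & (n_marginal >= 1))
    return pd.Series(expressed, index=calls.labels.index, name="expressed")


def top_n_by_mean(matrix: ExpressionMatrix, genotype: str, n: int) -> pd.Series:
    """Fallback expressed-gene selector: top-n genes by mean expression in one
    genotype, for use when detection calls are unavailable."""
    means = pd.Series(matrix.group_values(genotype).mean(axis=1), index=matrix.gene_ids)
    top = means.nlargest(n).index
    return pd.Series(matrix.gene_ids.isin(top), index=matrix.gene_ids, name="expressed")
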