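"""Restoration-to-wild-type tests, chromosome summaries, and category enrichment.

The signature of antagonistic ("yin-yang") regulation is that a gene set's
transcript levels shift in opposite directions in the two single mutants yet
return to wild-type levels in the double mutant.  That is quantified here by
per-set log2 fold-change profiles (box statistics match the percentile
convention of the expression figures: whiskers at 2.5/97.5, box at 25/75),
Student's t-tests of each genotype against WT, and hypergeometric enrichment
of gene sets in expression categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import hypergeometric_depletion, hypergeometric_overlap
from .core import CHROMOSOMES, ExpressionMatrix, GeneSet, ValidationError

BOX_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)

#: significance tiers used when flagging enrichment/depletion
STAR_TIERS = ((1e-10, "***"), (1e-3, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cutoff, mark in STAR_TIERS:
        if p < cutoff:
            return mark
    return ""


@dataclass
class FoldChangeProfile:
    """Per-genotype log2 fold changes vs WT for one gene set.

    ``per_genotype`` maps genotype → vector: one entry per gene for mutants;
    for WT itself, per-gene per-replicate deviations from the WT mean (so the
    WT box is centred on 0 and shows replicate scatter).
    """

    name: str
    genes: list
    per_genotype: dict[str, np.ndarray]
    box_stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.box_stats:
            self.box_stats = {
                g: dict(zip((f"p{q:g}" for q in BOX_PERCENTILES), np.percentile(v, BOX_PERCENTILES)))
                for g, v in self.per_genotype.items()
            }

    def median(self, genotype: str) -> float:
        return float(np.median(self.per_genotype[genotype]))


@dataclass
class RestorationVerdict:
    p_values: dict[str, float]        # genotype → Student's t p vs WT
    medians: dict[str, float]         # genotype → median log2FC vs WT
    alpha: float
    restored: bool

    @property
    def verdict(self) -> str:
        return "restored" if self.restored else "not_restored"


@dataclass
class EnrichmentResult:
    category: str
    n_set: int
    n_category: int
    universe: int
    observed: int
    expected: float
    p_enrichment: float
    p_depletion: float

    @property
    def enrichment_stars(self) -> str:
        return _stars(self.p_enrichment)

    @property
    def depletion_stars(self) -> str:
        return _stars(self.p_depletion)


def log2fc_profile(matrix: ExpressionMatrix, gene_set, genotypes=None) -> FoldChangeProfile:
    """Log2 fold change vs WT for every gene in the set, per genotype."""
    members = sorted(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    if not members:
        raise ValidationError("empty gene set")
    name = gene_set.name if isinstance(gene_set, GeneSet) else "gene_set"
    sub = matrix.subset_genes(members)
    genotypes = list(genotypes) if genotypes is not None else list(dict.fromkeys(matrix.samples["genotype"]))
    if "WT" not in genotypes:
        raise ValidationError("profiles are relative to WT, which is missing")
    wt = sub.group_values("WT")
    wt_mean = wt.mean(axis=1)
    per_genotype: dict[str, np.ndarray] = {}
    for g in genotypes:
        if g == "WT":
            per_genotype[g] = (wt - wt_mean[:, None]).ravel()
        else:
            per_genotype[g] = sub.group_values(g).mean(axis=1) - wt_mean
    return FoldChangeProfile(name=name, genes=members, per_genotype=per_genotype)


def restoration_test(
    matrix: ExpressionMatrix,
    gene_set,
    alpha: float = 1e-3,
    paired: bool = False,
    singles: tuple[str, str] = ("mes-4", "lin-54"),
    double: str = "double",
) -> RestorationVerdict:
    """Test whether the double mutant restores a gene set to WT levels.

    Each genotype's per-gene replicate-averaged log2 expression over the set
    is compared against WT's by a two-sample equal-variance Student's t-test
    (genes pooled as observations; ``paired=True`` switches to the paired
    variant).  Restored ⇔ both single mutants differ from WT (p < alpha) with
    opposite-signed median shifts AND the double mutant does not (p ≥ alpha).
    """
    members = sorted(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    if len(members) < 3:
        raise ValidationError(f"restoration test needs ≥3 genes, got {len(members)}")
    sub = matrix.subset_genes(members)
    wt = sub.group_values("WT").mean(axis=1)
    p_values: dict[str, float] = {}
    medians: dict[str, float] = {}
    for g in (*singles, double):
        vals = sub.group_values(g).mean(axis=1)
        if paired:
            _, p = stats.ttest_rel(vals, wt)
        else:
            _, p = stats.ttest_ind(vals, wt, equal_var=True)
        p_values[g] = float(p)
        medians[g] = float(np.median(vals - wt))
    s1, s2 = singles
    singles_differ = p_values[s1] < alpha and p_values[s2] < alpha
    opposite = medians[s1] * medians[s2] < 0
    double_matches_wt = p_values[double] >= alpha
    return RestorationVerdict(
        p_values=p_values,
        medians=medians,
        alpha=alpha,
        restored=bool(singles_differ and opposite and double_matches_wt),
    )


def chromosome_summary(
    matrix: ExpressionMatrix, expressed: pd.Series, genotypes=None
) -> dict[str, dict]:
    """Per-chromosome profiles of expressed genes plus WT absolute-level boxes.

    ``expressed`` is the boolean per-gene flag from WT detection calls (or a
    top-N selector when calls are absent).  Chromosomes with no expressed
    genes are omitted with a warning.
    """
    out: dict[str, dict] = {}
    chroms = matrix.genes["chrom"]
    for chrom in CHROMOSOMES:
        genes = matrix.gene_ids[(chroms == chrom).to_numpy() & expressed.loc[matrix.gene_ids].to_numpy()]
        if len(genes) == 0:
            warnings.warn(f"no expressed genes on chromosome {chrom}; omitted", stacklevel=2)
            continue
        gs = GeneSet(f"expressed-{chrom}", frozenset(genes), {"chrom": chrom})
        profile = log2fc_profile(matrix, gs, genotypes)
        wt_abs = matrix.subset_genes(sorted(genes)).group_values("WT").mean(axis=1)
        out[chrom] = {
            "n_genes": int(len(genes)),
            "profile": profile,
            "wt_expression_box": dict(
                zip((f"p{q:g}" for q in BOX_PERCENTILES), np.percentile(wt_abs, BOX_PERCENTILES))
            ),
            "wt_median_expression": float(np.median(wt_abs)),
        }
    return out


def category_enrichment(
    gene_set, category_map: pd.Series, universe
) -> list[EnrichmentResult]:
    """Observed vs expected membership of a gene set in each expression category.

    ``category_map`` assigns at most one label per universe gene; enrichment
    p is the upper hypergeometric tail at the observed count, depletion p the
    lower tail.
    """
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    universe = set(universe)
    if not members <= universe:
        raise ValidationError("gene set is not a subset of the universe")
    labeled = category_map[category_map.index.isin(universe)]
    n_universe = len(universe)
    n_set = len(members)
    results = []
    for category in sorted(labeled.dropna().unique()):
        cat_genes = set(labeled.index[labeled == category])
        observed = len(members & cat_genes)
        k = len(cat_genes)
        expected = n_set * k / n_universe
        upper = hypergeometric_overlap(n_set, k, observed, n_universe)
        p_dep = hypergeometric_depletion(n_set, k, observed, n_universe)
        results.append(
            EnrichmentResult(
                category=category,
                n_set=n_set,
                n_category=k,
                universe=n_universe,
                observed=observed,
                expected=expected,
                p_enrichment=upper.p,
                p_depletion=p_dep,
            )
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "p_enrichment": [r.p_enrichment for r in results],
            "p_depletion": [r.p_depletion for r in results],
            "enrichment_stars": [r.enrichment_stars for r in results],
            "depletion_stars": [r.depletion_stars for r in results],
        }
    )
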