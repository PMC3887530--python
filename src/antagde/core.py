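"""Core data containers for germline expression analysis.

The experiment contrasts four genotypes — wild type (``WT``), the *mes-4*
null, the *lin-54* null, and the *lin-54; mes-4* double mutant — each with
replicate log2 expression profiles of dissected germlines.  All downstream
analysis (moderated t contrasts, gene-class intersection, restoration tests)
operates on :class:`ExpressionMatrix`, which couples the genes × samples
value matrix with sample metadata (genotype, replicate) and gene metadata
(chromosome, coordinates, expression category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "mes-4", "lin-54", "double")
CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")
AUTOSOMES = ("I", "II", "III", "IV", "V")
DETECTION_LABELS = ("P", "M", "A")

#: the five reported two-group comparisons, each "B_vs_A" meaning mean(B) - mean(A)
CONTRASTS = (
    ("mes-4", "WT"),
    ("lin-54", "WT"),
    ("double", "mes-4"),
    ("double", "lin-54"),
    ("double", "WT"),
)


def contrast_label(group_b: str, group_a: str) -> str:
    return f"{group_b}_vs_{group_a}"


class ValidationError(ValueError):
    """Raised when a container or input file violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with sample and gene metadata.

    Parameters
    ----------
    values : DataFrame
        Genes × samples, finite log2 intensities.
    samples : DataFrame
        Indexed by sample id; must carry ``genotype`` and ``replicate``
        columns, one row per column of ``values``.
    genes : DataFrame
        Indexed by gene (or probe-set) id; must carry ``chrom``; may carry
        ``strand``, ``tss``, ``start``, ``end`` (1-based inclusive) and
        ``category``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValidationError(
                f"sample sheet does not match matrix columns; mismatched: {sorted(missing)}"
            )
        if "genotype" not in self.samples.columns:
            raise ValidationError("sample sheet lacks a 'genotype' column")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.index[~np.isfinite(self.values).all(axis=1)][:5].tolist()
            raise ValidationError(f"non-finite intensities, e.g. rows {bad}")
        if "chrom" in self.genes.columns:
            unknown = set(self.genes["chrom"]) - set(CHROMOSOMES)
            if unknown:
                raise ValidationError(f"unknown chromosome labels: {sorted(unknown)}")
        if not self.values.index.equals(self.genes.index):
            raise ValidationError("gene metadata index does not match matrix rows")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, genotype: str) -> list[str]:
        """Sample ids belonging to one genotype, in sheet order."""
        sel = self.samples.index[self.samples["genotype"] == genotype]
        if len(sel) == 0:
            raise ValidationError(f"genotype {genotype!r} absent from sample sheet")
        return list(sel)

    def group_values(self, genotype: str) -> np.ndarray:
        """Genes × replicates value block for one genotype."""
        return self.values[self.samples_of(genotype)].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.samples, self.genes.loc[gene_ids]
        )

    def with_values(self, new_values: np.ndarray) -> "ExpressionMatrix":
        vals = pd.DataFrame(new_values, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(vals, self.samples, self.genes)


@dataclass
class DetectionCalls:
    """Per-gene, per-sample Present/Marginal/Absent detection labels."""

    labels: pd.DataFrame  # genes × samples of "P"/"M"/"A"

    def __post_init__(self) -> None:
        arr = self.labels.to_numpy()
        bad = set(arr.ravel()) - set(DETECTION_LABELS)
        if bad:
            raise ValidationError(f"unknown detection labels: {sorted(bad)}")

    def restrict(self, sample_ids) -> "DetectionCalls":
        return DetectionCalls(self.labels[list(sample_ids)])


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection plus the rule that produced it."""

    name: str
    members: frozenset
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members

    def sorted_members(self) -> list:
        return sorted(self.members)

    def __and__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(
            f"{self.name}&{other.name}",
            self.members & other.members,
            {"intersection_of": [self.name, other.name]},
        )
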