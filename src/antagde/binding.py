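"""ChIP track scaling, replicate-consistent peaks, and binding-call analysis.

Coordinate conventions: annotation tables use 1-based inclusive gene
coordinates at the interface (``tss``, ``start``, ``end``); all interval
arithmetic is done internally in 0-based half-open coordinates, with the
conversions centralized in :func:`to_internal` / :func:`to_annotation`.

Binding rules:

* promoter-bound — some single peak overlaps the window from 500 bp
  upstream to 500 bp downstream of the TSS by at least 200 bp (the overlap
  threshold is per peak, not on the union of peaks);
* body-bound — the union of peaks covers at least half the gene body
  (the coverage fraction is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classify import hypergeometric_depletion, hypergeometric_overlap
from .core import GeneSet, ValidationError
from .restore import EnrichmentResult


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive [start, end] → 0-based half-open [start-1, end)."""
    return start_1based - 1, end_1based


def to_annotation(start_0based: int, end_half_open: int) -> tuple[int, int]:
    """0-based half-open → 1-based inclusive; inverse of :func:`to_internal`."""
    return start_0based + 1, end_half_open


@dataclass
class PeakSet:
    """Called peaks for one factor and replicate, 0-based half-open."""

    factor: str
    replicate: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        iv = self.intervals
        if (iv["start"] >= iv["end"]).any():
            bad = iv[iv["start"] >= iv["end"]].head(3)
            raise ValidationError(f"degenerate peaks (start ≥ end):\n{bad}")
        self.intervals = iv.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            out[chrom] = IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
        return out


@dataclass
class BindingCalls:
    """Per-gene promoter/body binding flags for one factor."""

    factor: str
    promoter_bound: pd.Series | None = None
    body_bound: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def bound_genes(self, where: str = "promoter") -> frozenset:
        flags = self.promoter_bound if where == "promoter" else self.body_bound
        if flags is None:
            raise ValidationError(f"no {where} calls for factor {self.factor}")
        return frozenset(flags.index[flags])


def scale_chip_track(values) -> np.ndarray:
    """Scale intensity ratios to MAD 1, then shift the median to 1."""
    values = np.asarray(values, dtype=float)
    if np.unique(values[np.isfinite(values)]).size < 2:
        raise ValidationError("track scaling needs ≥2 distinct finite values")
    if not np.isfinite(values).all():
        raise ValidationError("track contains non-finite values")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        raise ValidationError("median absolute deviation is zero; cannot scale")
    scaled = values / mad
    return scaled - np.median(scaled) + 1.0


def consistent_peaks(replicate_peaksets: list[PeakSet], reference: int = 0, min_overlap: int = 1) -> PeakSet:
    """Keep reference-replicate peaks supported by at least one other replicate.

    Support means ≥ ``min_overlap`` bp overlap with some peak in another
    replicate; retained peaks keep the reference replicate's coordinates.
    """
    if len(replicate_peaksets) < 2:
        raise ValidationError("replicate consistency needs ≥2 replicates")
    ref = replicate_peaksets[reference]
    others = [ps for i, ps in enumerate(replicate_peaksets) if i != reference]
    other_trees = [ps.trees() for ps in others]
    keep = []
    for row in ref.intervals.itertuples(index=False):
        supported = False
        for trees in other_trees:
            tree = trees.get(row.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(row.start, row.end):
                if min(row.end, hit.end) - max(row.start, hit.begin) >= min_overlap:
                    supported = True
                    break
            if supported:
                break
        if supported:
            keep.append(row)
    kept = pd.DataFrame(keep, columns=["chrom", "start", "end"])
    return PeakSet(factor=ref.factor, replicate=f"{ref.replicate}_consistent", intervals=kept)


def _require_columns(annotation: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation lacks columns {missing}")
    for c in cols:
        if annotation[c].isna().any():
            bad = annotation.index[annotation[c].isna()][:5].tolist()
            raise ValidationError(f"annotation column {c!r} undefined for genes {bad}")


def call_promoter_bound(
    peaks: PeakSet, annotation: pd.DataFrame, window: int = 500, min_overlap: int = 200
) -> BindingCalls:
    """Flag genes whose TSS±window region a single peak overlaps ≥ min_overlap bp.

    The window spans ``window`` bp upstream through ``window`` bp downstream
    of the TSS (strand-aware by construction; symmetric at the defaults, so
    orientation does not change the region).
    """
    _require_columns(annotation, ["chrom", "tss", "strand"])
    trees = peaks.trees()
    flags = {}
    for gene, row in annotation.iterrows():
        tss = int(row["tss"])
        # 1-based inclusive [tss - window, tss + window] → internal half-open
        w_start, w_end = to_internal(tss - window, tss + window)
        bound = False
        tree = trees.get(row["chrom"])
        if tree is not None:
            for hit in tree.overlap(w_start, w_end):
                if min(w_end, hit.end) - max(w_start, hit.begin) >= min_overlap:
                    bound = True
                    break
        flags[gene] = bound
    return BindingCalls(
        factor=peaks.factor,
        promoter_bound=pd.Series(flags, name=f"{peaks.factor}_promoter"),
        params={"window": window, "min_overlap": min_overlap},
    )


def call_body_bound(
    peaks: PeakSet, annotation: pd.DataFrame, min_fraction: float = 0.5
) -> BindingCalls:
    """Flag genes whose body is covered ≥ min_fraction by the union of peaks."""
    if not 0 < min_fraction <= 1:
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    _require_columns(annotation, ["chrom", "start", "end"])
    trees = peaks.trees()
    flags = {}
    for gene, row in annotation.iterrows():
        g_start, g_end = to_internal(int(row["start"]), int(row["end"]))
        length = g_end - g_start
        tree = trees.get(row["chrom"])
        covered = 0
        if tree is not None:
            segs = sorted(
                (max(g_start, hit.begin), min(g_end, hit.end)) for hit in tree.overlap(g_start, g_end)
            )
            last = g_start
            for s, e in segs:  # union length of clipped, sorted segments
                s = max(s, last)
                if e > s:
                    covered += e - s
                    last = e
        flags[gene] = covered / length >= min_fraction
    return BindingCalls(
        factor=peaks.factor,
        body_bound=pd.Series(flags, name=f"{peaks.factor}_body"),
        params={"min_fraction": min_fraction},
    )


def cobinding_venn(
    calls_a: BindingCalls,
    calls_b: BindingCalls,
    universe,
    where_a: str = "body",
    where_b: str = "promoter",
) -> dict:
    """Two-way Venn counts of bound genes plus hypergeometric overlap."""
    universe = frozenset(universe)
    bound_a = calls_a.bound_genes(where_a) & universe
    bound_b = calls_b.bound_genes(where_b) & universe
    raw_a = calls_a.bound_genes(where_a)
    raw_b = calls_b.bound_genes(where_b)
    if not (raw_a <= universe and raw_b <= universe):
        raise ValidationError("binding calls extend beyond the stated universe")
    test = hypergeometric_overlap(len(bound_a), len(bound_b), len(bound_a & bound_b), len(universe))
    return {
        "factor_a": calls_a.factor,
        "factor_b": calls_b.factor,
        "a_only": len(bound_a - bound_b),
        "b_only": len(bound_b - bound_a),
        "both": len(bound_a & bound_b),
        "neither": len(universe) - len(bound_a | bound_b),
        "overlap_test": test,
    }


def binding_enrichment_in_sets(
    calls: dict[str, frozenset], gene_sets: dict[str, GeneSet], universe
) -> list[EnrichmentResult]:
    """Observed vs expected bound-gene counts in each gene set, per factor.

    ``calls`` maps factor label → bound gene ids (promoter, body, or an
    intersection of factors, as the caller chooses).
    """
    universe = set(universe)
    results = []
    for set_name, gs in gene_sets.items():
        members = set(gs.members)
        if not members <= universe:
            raise ValidationError(f"gene set {set_name} is not a subset of the universe")
        for factor, bound in calls.items():
            bound_u = set(bound) & universe
            observed = len(members & bound_u)
            expected = len(members) * len(bound_u) / len(universe)
            res = EnrichmentResult(
                category=f"{factor} in {set_name}",
                n_set=len(members),
                n_category=len(bound_u),
                universe=len(universe),
                observed=observed,
                expected=expected,
                p_enrichment=hypergeometric_overlap(
                    len(members), len(bound_u), observed, len(universe)
                ).p,
                p_depletion=hypergeometric_depletion(
                    len(members), len(bound_u), observed, len(universe)
                ),
            )
            results.append(res)
    return results


def binding_calls_table(all_calls: list[BindingCalls]) -> pd.DataFrame:
    """Wide per-gene table of promoter/body flags across factors."""
    cols = {}
    for calls in all_calls:
        if calls.promoter_bound is not None:
            cols[f"{calls.factor}_promoter"] = calls.promoter_bound
        if calls.body_bound is not None:
            cols[f"{calls.factor}_body"] = calls.body_bound
    tab = pd.DataFrame(cols)
    tab.index.name = "gene"
    return tab
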