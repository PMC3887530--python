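"""Significance-intersection classification of antagonistically regulated genes.

The antagonistic classes are defined by intersecting significance calls from
two contrasts — the effect of losing MES-4 (mes-4 vs WT) and the effect of
additionally losing LIN-54 (double vs mes-4):

* X-up   — X-linked, up in mes-4 vs WT and down in double vs mes-4;
* A-up   — autosomal, the same sign pattern;
* A-down — autosomal, the mirrored pattern (down then up).

Genes significant in both contrasts with the SAME sign form the
non-antagonistic remainder.  Overlap significance is the exact upper-tail
hypergeometric probability, computed in log space so that vanishingly small
p-values remain representable as log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core import AUTOSOMES, GeneSet, ValidationError

Q_CUTOFF = 0.05


@dataclass
class OverlapTest:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p: float
    log10_p: float


@dataclass
class AnticorrelationResult:
    n: int
    slope: float
    intercept: float
    r: float
    p: float
    n_opposite: int
    fraction_opposite: float


def significant_set(
    contrast: pd.DataFrame,
    direction: str | None = None,
    chrom_filter=None,
    q_cutoff: float = Q_CUTOFF,
    name: str | None = None,
) -> GeneSet:
    """Genes at q ≤ cutoff, optionally filtered by sign and chromosome.

    Genes with log2FC exactly 0 carry no direction and never enter a
    directional set.
    """
    mask = contrast["q"].to_numpy() <= q_cutoff
    if direction is not None:
        if direction not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
        sign = 1.0 if direction == "up" else -1.0
        mask &= np.sign(contrast["log2fc"].to_numpy()) == sign
    if chrom_filter is not None:
        if "chrom" not in contrast.columns:
            raise ValidationError("contrast table has no 'chrom' column to filter on")
        mask &= contrast["chrom"].isin(set(chrom_filter)).to_numpy()
    members = frozenset(contrast.loc[mask, "gene"])
    return GeneSet(
        name or f"sig_{direction or 'any'}",
        members,
        provenance={
            "q_cutoff": q_cutoff,
            "direction": direction,
            "chrom_filter": sorted(chrom_filter) if chrom_filter else None,
        },
    )


def classify_antagonistic(
    contrast_mes4_vs_wt: pd.DataFrame,
    contrast_double_vs_mes4: pd.DataFrame,
    q_cutoff: float = Q_CUTOFF,
) -> dict[str, GeneSet]:
    """Build the X-up / A-up / A-down classes plus the same-sign remainder."""
    universe_a = set(contrast_mes4_vs_wt["gene"])
    universe_b = set(contrast_double_vs_mes4["gene"])
    if universe_a != universe_b:
        raise ValidationError(
            f"contrast gene universes differ ({len(universe_a ^ universe_b)} mismatched)"
        )

    def sig(contrast, direction, chroms):
        return significant_set(contrast, direction, chroms, q_cutoff).members

    prov = {"q_cutoff": q_cutoff, "contrasts": ["mes-4_vs_WT", "double_vs_mes-4"]}
    x_up = GeneSet(
        "X-up",
        frozenset(sig(contrast_mes4_vs_wt, "up", {"X"}) & sig(contrast_double_vs_mes4, "down", {"X"})),
        {**prov, "rule": "X-linked, up in mes-4 vs WT and down in double vs mes-4"},
    )
    a_up = GeneSet(
        "A-up",
        frozenset(
            sig(contrast_mes4_vs_wt, "up", AUTOSOMES) & sig(contrast_double_vs_mes4, "down", AUTOSOMES)
        ),
        {**prov, "rule": "autosomal, up in mes-4 vs WT and down in double vs mes-4"},
    )
    a_down = GeneSet(
        "A-down",
        frozenset(
            sig(contrast_mes4_vs_wt, "down", AUTOSOMES) & sig(contrast_double_vs_mes4, "up", AUTOSOMES)
        ),
        {**prov, "rule": "autosomal, down in mes-4 vs WT and up in double vs mes-4"},
    )
    sig_both = sig(contrast_mes4_vs_wt, None, None) & sig(contrast_double_vs_mes4, None, None)
    antagonistic = x_up.members | a_up.members | a_down.members
    # X-linked mirrored pattern is rare but belongs to neither named class
    same_sign = frozenset(
        (sig(contrast_mes4_vs_wt, "up", None) & sig(contrast_double_vs_mes4, "up", None))
        | (sig(contrast_mes4_vs_wt, "down", None) & sig(contrast_double_vs_mes4, "down", None))
    )
    return {
        "X-up": x_up,
        "A-up": a_up,
        "A-down": a_down,
        "non-antagonistic": GeneSet(
            "non-antagonistic",
            same_sign & sig_both,
            {**prov, "rule": "significant in both contrasts with the same sign"},
        ),
        "significant-both": GeneSet(
            "significant-both", frozenset(sig_both), {**prov, "rule": "q ≤ cutoff in both"}
        ),
        "antagonistic": GeneSet(
            "antagonistic", frozenset(antagonistic), {**prov, "rule": "union of the three classes"}
        ),
    }


def hypergeometric_overlap(n_a: int, n_b: int, n_overlap: int, universe: int) -> OverlapTest:
    """Exact upper-tail P(K ≥ overlap) for K ~ Hypergeometric(N, |A|, |B|)."""
    if n_a > universe or n_b > universe:
        raise ValidationError("set sizes exceed the universe")
    if n_overlap > min(n_a, n_b):
        raise ValidationError(
            f"overlap {n_overlap} exceeds min(|A|, |B|) = {min(n_a, n_b)}"
        )
    if n_overlap < max(0, n_a + n_b - universe):
        raise ValidationError("overlap below the minimum forced by the universe")
    support = np.arange(n_overlap, min(n_a, n_b) + 1)
    log_p = logsumexp(stats.hypergeom.logpmf(support, universe, n_a, n_b))
    log_p = min(log_p, 0.0)
    return OverlapTest(
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_overlap,
        universe=universe,
        p=float(np.exp(log_p)),
        log10_p=float(log_p / np.log(10.0)),
    )


def hypergeometric_depletion(n_a: int, n_b: int, n_overlap: int, universe: int) -> float:
    """Exact lower-tail P(K ≤ overlap), computed in log space like the upper."""
    if n_overlap > min(n_a, n_b):
        raise ValidationError("overlap exceeds min(|A|, |B|)")
    lo = max(0, n_a + n_b - universe)
    support = np.arange(lo, n_overlap + 1)
    log_p = logsumexp(stats.hypergeom.logpmf(support, universe, n_a, n_b))
    return float(np.exp(min(log_p, 0.0)))


def overlap_test(set_a: GeneSet, set_b: GeneSet, universe_size: int) -> OverlapTest:
    return hypergeometric_overlap(
        len(set_a), len(set_b), len(set_a.members & set_b.members), universe_size
    )


def anticorrelation(
    contrast_a: pd.DataFrame,
    contrast_b: pd.DataFrame,
    q_cutoff: float = Q_CUTOFF,
    chrom_filter=None,
) -> AnticorrelationResult:
    """OLS of contrast-B fold changes on contrast-A fold changes, restricted
    to genes significant (q ≤ cutoff) in both contrasts.

    Mirrors the scatter comparison of the mes-4 effect against the added
    lin-54 effect: a slope near −1 with large |R| means the two lesions move
    the same genes by similar amounts in opposite directions.
    """
    a = contrast_a.set_index("gene")
    b = contrast_b.set_index("gene")
    if set(a.index) != set(b.index):
        raise ValidationError("contrast gene universes differ")
    b = b.loc[a.index]
    mask = (a["q"].to_numpy() <= q_cutoff) & (b["q"].to_numpy() <= q_cutoff)
    if chrom_filter is not None:
        mask &= a["chrom"].isin(set(chrom_filter)).to_numpy()
    x = a.loc[mask, "log2fc"].to_numpy()
    y = b.loc[mask, "log2fc"].to_numpy()
    if x.size < 3:
        raise ValidationError(f"need ≥3 genes significant in both contrasts, got {x.size}")
    res = stats.linregress(x, y)
    opposite = int(((np.sign(x) == -np.sign(y)) & (x != 0)).sum())
    return AnticorrelationResult(
        n=int(x.size),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n_opposite=opposite,
        fraction_opposite=opposite / x.size,
    )


def antagonistic_fraction(n_significant_both: int, n_antagonistic: int) -> tuple[float, int]:
    """Percentage of jointly significant genes that are antagonistic.

    Returns (exact percentage, nearest-integer percentage); e.g. 203 of 205
    X-linked jointly significant genes → (99.02..., 99).
    """
    if n_significant_both == 0:
        raise ValidationError("no genes significant in both contrasts")
    if n_antagonistic > n_significant_both:
        raise ValidationError("antagonistic count exceeds jointly significant count")
    exact = 100.0 * n_antagonistic / n_significant_both
    return exact, int(round(exact))
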