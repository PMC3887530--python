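"""Model/Results interface over the four-genotype germline experiment.

:class:`GermlineAntagonismModel` wraps a validated expression bundle;
``fit()`` runs the full analysis — optional quantile normalization, five
moderated-t contrasts with per-contrast q-values, significance-intersection
classification into the X-up / A-up / A-down antagonistic classes, overlap
significance, fold-change anti-correlation, restoration tests, and (when
detection calls are given) chromosome-wide summaries — returning a
:class:`GermlineAntagonismResults` whose ``summary()`` prints the headline
numbers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as adio
from .classify import (
    AnticorrelationResult,
    OverlapTest,
    anticorrelation,
    antagonistic_fraction,
    classify_antagonistic,
    significant_set,
)
from .core import AUTOSOMES, DetectionCalls, ExpressionMatrix, GeneSet, ValidationError
from .de import run_all_contrasts
from .normalize import call_expressed, quantile_normalize
from .restore import (
    FoldChangeProfile,
    RestorationVerdict,
    chromosome_summary,
    log2fc_profile,
    restoration_test,
)


class GermlineAntagonismModel:
    """Antagonistic-regulation analysis of a WT / mes-4 / lin-54 / double design.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2 expression with genotype/replicate sample metadata and
        chromosome gene metadata.
    calls : DetectionCalls, optional
        Detection labels used to define expressed genes (WT replicates).
    q_cutoff : float
        Per-contrast significance cutoff on the q-value.
    alpha : float
        Significance level of the restoration Student's t-tests.
    normalize : bool
        Quantile-normalize jointly across all samples before fitting.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        calls: DetectionCalls | None = None,
        q_cutoff: float = 0.05,
        alpha: float = 1e-3,
        normalize: bool = True,
        pi0_smoother: str = "poly",
    ) -> None:
        self.matrix = matrix
        self.calls = calls
        self.q_cutoff = q_cutoff
        self.alpha = alpha
        self.normalize = normalize
        self.pi0_smoother = pi0_smoother

    @classmethod
    def from_files(
        cls, matrix_path, sample_sheet_path, annotation_path, calls_path=None, **kwargs
    ) -> "GermlineAntagonismModel":
        matrix = adio.read_expression_matrix(matrix_path, sample_sheet_path, annotation_path)
        calls = adio.read_detection_calls(calls_path) if calls_path else None
        return cls(matrix, calls=calls, **kwargs)

    def fit(self) -> "GermlineAntagonismResults":
        matrix = quantile_normalize(self.matrix) if self.normalize else self.matrix
        contrasts = run_all_contrasts(matrix, smoother=self.pi0_smoother)
        gene_sets = classify_antagonistic(
            contrasts["mes-4_vs_WT"], contrasts["double_vs_mes-4"], q_cutoff=self.q_cutoff
        )

        chroms = matrix.genes["chrom"]
        n_x = int((chroms == "X").sum())
        n_auto = int(chroms.isin(AUTOSOMES).sum())
        m4, dm4 = contrasts["mes-4_vs_WT"], contrasts["double_vs_mes-4"]
        overlaps = {
            "X-up": _overlap_for(gene_sets["X-up"], m4, dm4, {"X"}, n_x, self.q_cutoff),
            "A-up": _overlap_for(gene_sets["A-up"], m4, dm4, AUTOSOMES, n_auto, self.q_cutoff, "up"),
            "A-down": _overlap_for(gene_sets["A-down"], m4, dm4, AUTOSOMES, n_auto, self.q_cutoff, "down"),
        }

        fractions = {}
        for label, chrom_filter in (("X", {"X"}), ("autosomes", AUTOSOMES)):
            both = _significant_both(m4, dm4, chrom_filter, self.q_cutoff)
            n_ant = len(gene_sets["antagonistic"].members & both)
            if both:
                exact, rounded = antagonistic_fraction(len(both), n_ant)
                fractions[label] = {
                    "n_significant_both": len(both),
                    "n_antagonistic": n_ant,
                    "percent": exact,
                    "percent_rounded": rounded,
                }

        anticorr: dict[str, AnticorrelationResult] = {}
        for label, chrom_filter in (("autosomes", AUTOSOMES), ("X", {"X"})):
            try:
                anticorr[label] = anticorrelation(m4, dm4, self.q_cutoff, chrom_filter)
            except ValidationError:
                pass

        profiles: dict[str, FoldChangeProfile] = {}
        verdicts: dict[str, RestorationVerdict] = {}
        for name in ("X-up", "A-up", "A-down"):
            gs = gene_sets[name]
            if len(gs) >= 3:
                profiles[name] = log2fc_profile(matrix, gs)
                verdicts[name] = restoration_test(matrix, gs, alpha=self.alpha)

        expressed = None
        chrom_profiles = None
        if self.calls is not None:
            wt_calls = self.calls.restrict(matrix.samples_of("WT"))
            expressed = call_expressed(wt_calls)
            chrom_profiles = chromosome_summary(matrix, expressed)

        return GermlineAntagonismResults(
            model=self,
            normalized=matrix,
            contrasts=contrasts,
            gene_sets=gene_sets,
            overlaps=overlaps,
            fractions=fractions,
            anticorrelation=anticorr,
            profiles=profiles,
            restoration=verdicts,
            expressed=expressed,
            chromosome_profiles=chrom_profiles,
        )


def _significant_both(m4, dm4, chrom_filter, q_cutoff) -> frozenset:
    a = significant_set(m4, None, chrom_filter, q_cutoff).members
    b = significant_set(dm4, None, chrom_filter, q_cutoff).members
    return a & b


def _overlap_for(gs, m4, dm4, chrom_filter, universe, q_cutoff, direction_m4="up") -> OverlapTest:
    from .classify import hypergeometric_overlap

    other = "down" if direction_m4 == "up" else "up"
    set_a = significant_set(m4, direction_m4, chrom_filter, q_cutoff).members
    set_b = significant_set(dm4, other, chrom_filter, q_cutoff).members
    return hypergeometric_overlap(len(set_a), len(set_b), len(gs), universe)


@dataclass
class GermlineAntagonismResults:
    """Fitted results: contrast tables, gene classes, and diagnostics."""

    model: GermlineAntagonismModel
    normalized: ExpressionMatrix
    contrasts: dict[str, pd.DataFrame]
    gene_sets: dict[str, GeneSet]
    overlaps: dict[str, OverlapTest]
    fractions: dict[str, dict]
    anticorrelation: dict[str, AnticorrelationResult]
    profiles: dict[str, FoldChangeProfile]
    restoration: dict[str, RestorationVerdict]
    expressed: pd.Series | None = None
    chromosome_profiles: dict | None = None
    extras: dict = field(default_factory=dict)

    def significant_counts(self) -> pd.DataFrame:
        """Up/down counts at the q cutoff per contrast, split X vs autosomes."""
        rows = []
        for label, tab in self.contrasts.items():
            for chrom_label, chrom_filter in (("X", {"X"}), ("autosomes", set(AUTOSOMES))):
                sub = tab[tab["chrom"].isin(chrom_filter)]
                sig = sub["q"] <= self.model.q_cutoff
                rows.append(
                    {
                        "contrast": label,
                        "chromosomes": chrom_label,
                        "up": int((sig & (sub["log2fc"] > 0)).sum()),
                        "down": int((sig & (sub["log2fc"] < 0)).sum()),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = _io.StringIO()
        w = buf.write
        w("Germline antagonistic-regulation analysis\n")
        w("=========================================\n")
        w(f"genes: {self.normalized.n_genes}   samples: {self.normalized.n_samples}   ")
        w(f"q cutoff: {self.model.q_cutoff}   restoration alpha: {self.model.alpha}\n\n")
        w("Significant genes per contrast (q <= cutoff):\n")
        w(self.significant_counts().to_string(index=False))
        w("\n\nAntagonistic gene classes:\n")
        for name in ("X-up", "A-up", "A-down"):
            gs = self.gene_sets[name]
            ov = self.overlaps.get(name)
            extra = f"   overlap log10 p = {ov.log10_p:.1f}" if ov and len(gs) else ""
            w(f"  {name:7s} {len(gs):5d} genes{extra}\n")
        for label, fr in self.fractions.items():
            w(
                f"  {label}: {fr['n_antagonistic']} of {fr['n_significant_both']} jointly "
                f"significant genes antagonistic ({fr['percent_rounded']}%)\n"
            )
        if self.anticorrelation:
            w("\nFold-change anti-correlation (double vs mes-4 on mes-4 vs WT):\n")
            for label, ac in self.anticorrelation.items():
                w(
                    f"  {label}: slope {ac.slope:.2f}, R {abs(ac.r):.2f} "
                    f"(n={ac.n}, opposite-signed {100 * ac.fraction_opposite:.0f}%)\n"
                )
        if self.restoration:
            w("\nRestoration to wild type in the double mutant:\n")
            for name, v in self.restoration.items():
                ps = ", ".join(f"{g}: p={p:.2e}" for g, p in v.p_values.items())
                w(f"  {name:7s} {v.verdict:13s} ({ps})\n")
        if self.chromosome_profiles:
            w("\nWT median expression of expressed genes per chromosome:\n")
            for chrom, info in self.chromosome_profiles.items():
                w(
                    f"  {chrom:3s} n={info['n_genes']:5d}  median log2 = "
                    f"{info['wt_median_expression']:.2f}\n"
                )
        return buf.getvalue()

    def summary_dict(self) -> dict:
        """Machine-readable headline numbers (JSON-serializable)."""
        out = {
            "n_genes": int(self.normalized.n_genes),
            "q_cutoff": self.model.q_cutoff,
            "significant_counts": self.significant_counts().to_dict(orient="records"),
            "class_sizes": {k: len(self.gene_sets[k]) for k in ("X-up", "A-up", "A-down", "non-antagonistic")},
            "fractions": self.fractions,
            "anticorrelation": {
                k: {
                    "n": v.n,
                    "slope": v.slope,
                    "intercept": v.intercept,
                    "r": v.r,
                    "p": v.p,
                    "fraction_opposite": v.fraction_opposite,
                }
                for k, v in self.anticorrelation.items()
            },
            "overlaps": {
                k: {"log10_p": v.log10_p, "overlap": v.n_overlap} for k, v in self.overlaps.items()
            },
            "restoration": {
                k: {"verdict": v.verdict, "p_values": v.p_values, "medians": v.medians}
                for k, v in self.restoration.items()
            },
        }
        if self.chromosome_profiles:
            out["chromosomes"] = {
                c: {
                    "n_expressed": info["n_genes"],
                    "wt_median_expression": info["wt_median_expression"],
                    "median_log2fc": {
                        g: info["profile"].median(g) for g in info["profile"].per_genotype
                    },
                }
                for c, info in self.chromosome_profiles.items()
            }
        return out

    def plot_profile(self, name: str, ax=None):
        """Box plot of a gene class's fold-change profile (needs matplotlib)."""
        import matplotlib.pyplot as plt

        profile = self.profiles[name]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        genotypes = list(profile.per_genotype)
        data = [profile.per_genotype[g] for g in genotypes]
        ax.boxplot(data, labels=genotypes, whis=(2.5, 97.5), showfliers=False)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("log2 fold change vs WT")
        ax.set_title(f"{name} ({len(profile.genes)} genes)")
        return ax
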