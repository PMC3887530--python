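"""Synthetic germline-expression experiments with planted antagonistic classes.

The generator emulates the structure the analysis assumes: four genotypes
(WT, mes-4, lin-54, double) × 3 replicates of log2 expression over genes on
chromosomes I–V and X, with

* planted X-up / A-up genes shifted +effect in mes-4 and −effect in lin-54,
  cancelling in the double mutant (A-down mirrored);
* "other-DE" genes shifted in mes-4 only, with the shift carried into the
  double mutant, so they are significant in mes-4 vs WT but not in
  double vs mes-4;
* per-gene variances drawn from a scaled-inverse-chi-square hierarchy (prior
  df ``var_prior_df``, scale ``noise_sd``²) so the moderated-t model is
  exactly the generating model;
* chromosome-wide dampening of X-linked baseline expression;
* Present/Marginal/Absent detection calls thresholded on the true baseline
  with label noise;
* promoter peaks enriched at germline-category genes, per factor and ChIP
  replicate, placed so each planted peak overlaps the TSS±500 bp window by
  well over 200 bp (MES-4 peaks additionally span the gene body).

All randomness flows from one master seed through named substreams, so a
fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AUTOSOMES, CHROMOSOMES, DetectionCalls, ExpressionMatrix, GeneSet, ValidationError
from .binding import PeakSet

CLASSES = ("X-up", "A-up", "A-down", "other-DE", "null")
CATEGORIES = ("germline-specific", "germline-enriched", "ubiquitous", "soma-specific", "other")
GERMLINE_CATEGORIES = frozenset({"germline-specific", "germline-enriched"})

_DEFAULT_CHROM_WEIGHTS = {"I": 0.17, "II": 0.17, "III": 0.17, "IV": 0.17, "V": 0.17, "X": 0.15}

#: category label distribution conditional on planted class
_DEFAULT_CATEGORY_PROBS = {
    "X-up": {"germline-specific": 0.15, "germline-enriched": 0.30, "ubiquitous": 0.35, "soma-specific": 0.05, "other": 0.15},
    "A-up": {"germline-specific": 0.02, "germline-enriched": 0.05, "ubiquitous": 0.35, "soma-specific": 0.35, "other": 0.23},
    "A-down": {"germline-specific": 0.25, "germline-enriched": 0.45, "ubiquitous": 0.20, "soma-specific": 0.02, "other": 0.08},
    "other-DE": {"germline-specific": 0.05, "germline-enriched": 0.10, "ubiquitous": 0.30, "soma-specific": 0.15, "other": 0.40},
    "null": {"germline-specific": 0.05, "germline-enriched": 0.10, "ubiquitous": 0.30, "soma-specific": 0.15, "other": 0.40},
}

GENE_LENGTH = 2000     # bp, uniform synthetic gene bodies
GENE_SPACING = 4000    # bp between consecutive gene starts on a chromosome
CHROM_OFFSET = 5000    # bp before the first gene


@dataclass
class SimConfig:
    """Generator parameters; defaults are the documented study conditions."""

    n_genes: int = 6000
    chrom_weights: dict = field(default_factory=lambda: dict(_DEFAULT_CHROM_WEIGHTS))
    n_replicates: int = 3
    baseline_mean: float = 7.0     # log2 intensity
    baseline_sd: float = 1.5       # log2 units, gene-level spread
    noise_sd: float = 0.25         # log2 units: prior scale s0 of replicate noise
    var_prior_df: float = 4.0      # d0 of the scaled-inverse-chi-square hierarchy
    class_sizes: dict = field(
        default_factory=lambda: {"X-up": 200, "A-up": 200, "A-down": 200, "other-DE": 200}
    )
    effect_size: float = 1.0       # log2 units, magnitude of single-mutant shifts
    double_restoration: float = 0.0  # residual fraction of the mes-4 effect in the double
    x_dampening: float = 1.0       # log2 units subtracted from X-linked baselines
    category_probs: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CATEGORY_PROBS.items()})
    peak_enrichment: float = 0.8   # P(promoter peak | germline category)
    peak_background: float = 0.02  # P(promoter peak | other category)
    n_background_peaks: int = 200  # intergenic noise peaks per factor/replicate
    n_chip_replicates: int = 2
    factors: tuple = ("MES-4", "LIN-54", "EFL-1")
    call_absent_below: float = 6.0   # baseline thresholds for P/M/A calls
    call_marginal_below: float = 6.5
    call_label_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_sizes.values()) > self.n_genes:
            raise ValidationError("planted class sizes exceed n_genes")
        if abs(sum(self.chrom_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("chromosome weights must sum to 1")
        for name in ("baseline_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("peak_enrichment", "peak_background", "call_label_noise"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        unknown = set(self.class_sizes) - set(CLASSES)
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene class, effects, category, binding flags."""

    table: pd.DataFrame  # index gene; class, effect per genotype, category, bound_<factor>

    def genes_of_class(self, cls: str) -> GeneSet:
        genes = self.table.index[self.table["class"] == cls]
        return GeneSet(f"planted-{cls}", frozenset(genes), {"planted": True})


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _assign_chromosomes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    chroms = list(cfg.chrom_weights)
    counts = (np.array([cfg.chrom_weights[c] for c in chroms]) * cfg.n_genes).astype(int)
    counts[0] += cfg.n_genes - counts.sum()  # absorb rounding
    assigned = np.repeat(chroms, counts)
    rng.shuffle(assigned)
    return assigned


def simulate_experiment(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, DetectionCalls, SimTruth]:
    """Generate (expression matrix, annotation, detection calls, truth)."""
    cfg = config
    rngs = _substreams(
        cfg.seed,
        ("chrom", "classes", "baseline", "variance", "category", "binding",
         "noise-WT", "noise-mes-4", "noise-lin-54", "noise-double", "calls"),
    )
    gene_ids = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene")
    chrom = _assign_chromosomes(cfg, rngs["chrom"])

    # plant classes respecting chromosome constraints
    classes = np.full(cfg.n_genes, "null", dtype=object)
    x_idx = np.flatnonzero(chrom == "X")
    a_idx = np.flatnonzero(np.isin(chrom, AUTOSOMES))
    n_xup = cfg.class_sizes.get("X-up", 0)
    if n_xup > x_idx.size:
        raise ValidationError(f"X-up class ({n_xup}) exceeds X-linked capacity ({x_idx.size})")
    n_auto = sum(cfg.class_sizes.get(k, 0) for k in ("A-up", "A-down", "other-DE"))
    if n_auto > a_idx.size:
        raise ValidationError(f"autosomal classes ({n_auto}) exceed autosomal capacity ({a_idx.size})")
    pick_x = rngs["classes"].choice(x_idx, size=n_xup, replace=False)
    classes[pick_x] = "X-up"
    pick_a = rngs["classes"].choice(a_idx, size=n_auto, replace=False)
    offset = 0
    for cls in ("A-up", "A-down", "other-DE"):
        k = cfg.class_sizes.get(cls, 0)
        classes[pick_a[offset : offset + k]] = cls
        offset += k

    # planted log2 effects relative to WT
    e = cfg.effect_size
    r = cfg.double_restoration
    eff = pd.DataFrame(0.0, index=gene_ids, columns=["mes-4", "lin-54", "double"])
    up_like = np.isin(classes, ["X-up", "A-up"])
    eff.loc[up_like, "mes-4"] = +e
    eff.loc[up_like, "lin-54"] = -e
    eff.loc[up_like, "double"] = r * e
    down = classes == "A-down"
    eff.loc[down, "mes-4"] = -e
    eff.loc[down, "lin-54"] = +e
    eff.loc[down, "double"] = -r * e
    other = classes == "other-DE"
    other_sign = rngs["classes"].choice([-1.0, 1.0], size=int(other.sum()))
    eff.loc[other, "mes-4"] = other_sign * e
    eff.loc[other, "double"] = other_sign * e  # carried over: no added lin-54 effect

    baseline = rngs["baseline"].normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    baseline = baseline - np.where(chrom == "X", cfg.x_dampening, 0.0)
    d0, s0 = cfg.var_prior_df, cfg.noise_sd
    gene_sd = np.sqrt(d0 * s0**2 / rngs["variance"].chisquare(d0, cfg.n_genes))

    genotypes = ("WT", "mes-4", "lin-54", "double")
    columns, values, sample_rows = [], [], []
    for g in genotypes:
        shift = np.zeros(cfg.n_genes) if g == "WT" else eff[g].to_numpy()
        noise = rngs[f"noise-{g}"].normal(
            0.0, gene_sd[:, None], (cfg.n_genes, cfg.n_replicates)
        )
        block = baseline[:, None] + shift[:, None] + noise
        for rep in range(1, cfg.n_replicates + 1):
            columns.append(f"{g}_r{rep}")
            sample_rows.append({"sample": f"{g}_r{rep}", "genotype": g, "replicate": rep})
            values.append(block[:, rep - 1])
    matrix_df = pd.DataFrame(np.column_stack(values), index=gene_ids, columns=columns)
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # annotation: genes laid out sequentially per chromosome, alternating strand
    ann = pd.DataFrame(index=gene_ids)
    ann["chrom"] = chrom
    position = np.zeros(cfg.n_genes, dtype=int)
    for c in CHROMOSOMES:
        idx = np.flatnonzero(chrom == c)
        position[idx] = np.arange(idx.size)
    ann["strand"] = np.where(position % 2 == 0, "+", "-")
    ann["start"] = CHROM_OFFSET + position * GENE_SPACING + 1  # 1-based inclusive
    ann["end"] = ann["start"] + GENE_LENGTH - 1
    ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"])

    categories = np.empty(cfg.n_genes, dtype=object)
    for cls in CLASSES:
        idx = np.flatnonzero(classes == cls)
        probs = cfg.category_probs[cls]
        labels = list(probs)
        p = np.array([probs[k] for k in labels], dtype=float)
        p = p / p.sum()
        categories[idx] = rngs["category"].choice(labels, size=idx.size, p=p)
    ann["category"] = categories

    # detection calls from the true baseline with label noise
    true_label = np.where(
        baseline < cfg.call_absent_below,
        "A",
        np.where(baseline < cfg.call_marginal_below, "M", "P"),
    )
    calls_rng = rngs["calls"]
    call_cols = {}
    for col in columns:
        labels = true_label.copy()
        flip = calls_rng.random(cfg.n_genes) < cfg.call_label_noise
        labels[flip] = calls_rng.choice(["P", "M", "A"], size=int(flip.sum()))
        call_cols[col] = labels
    calls = DetectionCalls(pd.DataFrame(call_cols, index=gene_ids))

    # promoter-binding flags per factor, enriched at germline-category genes
    germline = np.isin(categories, list(GERMLINE_CATEGORIES))
    truth = pd.DataFrame(index=gene_ids)
    truth["class"] = classes
    truth["chrom"] = chrom
    truth["category"] = categories
    for g in ("mes-4", "lin-54", "double"):
        truth[f"effect_{g}"] = eff[g].to_numpy()
    truth["baseline"] = baseline
    truth["gene_sd"] = gene_sd
    for factor in cfg.factors:
        p_bound = np.where(germline, cfg.peak_enrichment, cfg.peak_background)
        truth[f"bound_{factor}"] = rngs["binding"].random(cfg.n_genes) < p_bound

    matrix = ExpressionMatrix(matrix_df, samples, ann)
    return matrix, ann, calls, SimTruth(truth)


def simulate_peaks(truth: SimTruth, annotation: pd.DataFrame, config: SimConfig) -> dict[str, list[PeakSet]]:
    """ChIP peaks per factor per replicate from the planted binding flags.

    Flagged genes receive, in every ChIP replicate, a peak centred near the
    TSS (jitter ±100 bp, width 800 bp → ≥700 bp overlap with the TSS±500
    window, comfortably past the 200 bp rule); MES-4 peaks instead span the
    whole gene body plus the promoter.  Background peaks are placed
    uniformly over each chromosome's span.
    """
    if annotation["tss"].isna().any():
        raise ValidationError("annotation TSS undefined for some genes")
    cfg = config
    rngs = _substreams(cfg.seed + 1_000_003, tuple(f"peaks-{f}" for f in cfg.factors))
    chrom_span = {
        c: int(annotation.loc[annotation["chrom"] == c, "end"].max()) + CHROM_OFFSET
        for c in annotation["chrom"].unique()
    }
    out: dict[str, list[PeakSet]] = {}
    for factor in cfg.factors:
        rng = rngs[f"peaks-{factor}"]
        bound = truth.table[f"bound_{factor}"]
        reps = []
        for rep in range(1, cfg.n_chip_replicates + 1):
            rows = []
            for gene in truth.table.index[bound]:
                row = annotation.loc[gene]
                tss0 = int(row["tss"]) - 1  # internal 0-based
                jitter = int(rng.integers(-100, 101))
                if factor == "MES-4":
                    start = min(int(row["start"]) - 1, tss0 - 400 + jitter)
                    end = max(int(row["end"]), tss0 + 400 + jitter)
                else:
                    start, end = tss0 - 400 + jitter, tss0 + 400 + jitter
                rows.append((row["chrom"], max(start, 0), end))
            for _ in range(cfg.n_background_peaks):
                chroms = list(chrom_span)
                c = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, max(chrom_span[c] - 400, 1)))
                rows.append((c, start, start + 400))
            intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            reps.append(PeakSet(factor=factor, replicate=f"rep{rep}", intervals=intervals))
        out[factor] = reps
    return out


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """The same conditions with every planted effect removed (for calibration)."""
    base = config or SimConfig()
    return replace(base, effect_size=0.0, x_dampening=0.0, **overrides)
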