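"""Two-group moderated t-tests with empirical-Bayes variance shrinkage.

Model: for gene g the replicate log2 intensities in each group are Gaussian
with common within-group variance sigma_g^2, and the gene variances follow a
scaled-inverse-chi-square prior,

    1 / sigma_g^2  ~  chi2_{d0} / (d0 * s0^2).

The pooled residual variance s_g^2 (d_g = n_A + n_B - 2 df) is shrunk toward
the prior scale via its posterior mean

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t = log2FC / (s~_g * sqrt(1/n_A + 1/n_B)) is referred to a
t distribution with d0 + d_g degrees of freedom (standard normal when
d0 = inf).  The hyperparameters (d0, s0^2) are estimated by the method of
moments on log s_g^2, using the digamma/trigamma moment identities of the
log-chi-square distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import CONTRASTS, ExpressionMatrix, ValidationError, contrast_label
from .qvalue import QValueResult, estimate_qvalues


@dataclass
class ContrastFit:
    """Per-gene summary statistics of one two-group comparison."""

    label: str
    gene_ids: pd.Index
    log2fc: np.ndarray   # mean(B) - mean(A)
    s2: np.ndarray       # pooled within-group variance
    df_residual: float   # n_A + n_B - 2
    n_a: int
    n_b: int


@dataclass
class EBayesHyperparams:
    """Prior df and scale of the variance hierarchy, plus posterior variances."""

    d0: float            # prior degrees of freedom; may be inf
    s0_squared: float    # prior variance scale
    s2_post: np.ndarray  # posterior (shrunken) variances, one per gene


def fit_contrast(matrix: ExpressionMatrix, group_a: str, group_b: str) -> ContrastFit:
    """Per-gene fold change and pooled variance for genotype B vs genotype A."""
    a = matrix.group_values(group_a)
    b = matrix.group_values(group_b)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"each group needs ≥2 replicates (got {group_a}: {n_a}, {group_b}: {n_b})"
        )
    if set(matrix.samples_of(group_a)) & set(matrix.samples_of(group_b)):
        raise ValidationError("contrast groups share samples")
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n_a + n_b - 2
    return ContrastFit(
        label=contrast_label(group_b, group_a),
        gene_ids=matrix.gene_ids,
        log2fc=log2fc,
        s2=ss / df,
        df_residual=float(df),
        n_a=n_a,
        n_b=n_b,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_hyperparams(s2, df_residual: float) -> EBayesHyperparams:
    """Method-of-moments fit of (d0, s0^2) from the observed variances.

    On z_g = log s_g^2 the hierarchy gives
        E[z] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(d/2) + psi'(d0/2),
    so the excess of Var[z] over the sampling term psi'(d/2) identifies d0
    via the trigamma inverse.  No excess dispersion means d0 = inf and every
    posterior variance collapses to s0^2.  Genes with s_g^2 = 0 are excluded
    from estimation but still receive a (strictly positive) posterior
    variance.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() == 0:
        raise ValidationError("all residual variances are zero")
    if positive.sum() < 10:
        raise ValidationError(
            f"need ≥10 genes with positive variance to estimate the prior "
            f"(got {int(positive.sum())})"
        )
    d = float(df_residual)
    z = np.log(s2[positive])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_squared = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_squared + d * s2) / (d0 + d)
    else:
        d0 = np.inf
        s0_squared = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s0_squared)
    return EBayesHyperparams(d0=float(d0), s0_squared=s0_squared, s2_post=s2_post)


def moderated_t_test(
    fit: ContrastFit, hyperparams: EBayesHyperparams | None
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values for one contrast.

    Passing ``hyperparams=None`` bypasses moderation and yields the ordinary
    pooled two-sample Student t-test.
    """
    se_factor = np.sqrt(1.0 / fit.n_a + 1.0 / fit.n_b)
    if hyperparams is None:
        s2, df_total = fit.s2, fit.df_residual
    else:
        s2, df_total = hyperparams.s2_post, hyperparams.d0 + fit.df_residual
    s = np.sqrt(s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.log2fc / (s * se_factor)
    zero_s = s == 0
    if zero_s.any():
        warnings.warn(
            f"{int(zero_s.sum())} genes with zero residual standard error; "
            "p set to 0 where the fold change is nonzero",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.where(zero_s, np.sign(fit.log2fc) * np.inf, t)
        t = np.where(zero_s & (fit.log2fc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def contrast_table(
    fit: ContrastFit,
    hyperparams: EBayesHyperparams | None,
    genes: pd.DataFrame | None = None,
    smoother: str = "poly",
) -> tuple[pd.DataFrame, QValueResult]:
    """Assemble the per-gene results table (gene, chrom, log2FC, t, p, q,
    direction) for one contrast; q-values are computed within the contrast."""
    t, p = moderated_t_test(fit, hyperparams)
    qres = estimate_qvalues(p, smoother=smoother)
    direction = np.where(fit.log2fc > 0, "up", np.where(fit.log2fc < 0, "down", "none"))
    tab = pd.DataFrame(
        {
            "gene": fit.gene_ids,
            "log2fc": fit.log2fc,
            "t": t,
            "p": p,
            "q": qres.q,
            "direction": direction,
        }
    )
    if genes is not None and "chrom" in genes.columns:
        tab.insert(1, "chrom", genes.loc[fit.gene_ids, "chrom"].to_numpy())
    return tab.reset_index(drop=True), qres


def run_all_contrasts(
    matrix: ExpressionMatrix, smoother: str = "poly", moderate: bool = True
) -> dict[str, pd.DataFrame]:
    """The five reported comparisons, each an independent two-group fit.

    Returns a mapping contrast label → results table.  Hyperparameters are
    estimated per contrast on its own pooled variances; q-values are likewise
    per contrast.
    """
    genotypes = set(matrix.samples["genotype"])
    needed = {g for pair in CONTRASTS for g in pair}
    missing = needed - genotypes
    if missing:
        raise ValidationError(f"missing genotypes: {sorted(missing)}")
    tables: dict[str, pd.DataFrame] = {}
    for group_b, group_a in CONTRASTS:
        fit = fit_contrast(matrix, group_a, group_b)
        hyper = estimate_hyperparams(fit.s2, fit.df_residual) if moderate else None
        tab, _ = contrast_table(fit, hyper, genes=matrix.genes, smoother=smoother)
        tables[fit.label] = tab
    return tables
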