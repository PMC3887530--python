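"""Storey q-value estimation of the false discovery rate.

Given m p-values, the proportion of true nulls is estimated from the tail
counts pi0(lambda) = #{p_i > lambda} / (m (1 - lambda)) on the grid
lambda = 0.05, 0.10, ..., 0.95, smoothed (cubic polynomial by default, a
smoothing spline optionally) and read off at lambda = 0.95, clipped to
(0, 1].  The q-value of the i-th ordered p-value is

    q_(i) = min_{j >= i}  pi0 * m * p_(j) / j,   capped at 1,

which is monotone non-decreasing in p by construction.  Below 100 p-values
there is too little tail to smooth and pi0 is fixed at 1 (the estimate then
coincides with Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class QValueResult:
    q: np.ndarray
    pi0: float
    lambdas: np.ndarray
    pi0_lambda: np.ndarray


def _smooth_pi0(lambdas: np.ndarray, pi0_lambda: np.ndarray, smoother: str) -> float:
    if smoother == "poly":
        coef = np.polyfit(lambdas, pi0_lambda, deg=3)
        return float(np.polyval(coef, lambdas[-1]))
    if smoother == "spline":
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(lambdas, pi0_lambda, k=3)
        return float(spl(lambdas[-1]))
    raise ValidationError(f"unknown pi0 smoother {smoother!r}")


def estimate_qvalues(p, smoother: str = "poly") -> QValueResult:
    """Estimate per-test q-values and the null proportion pi0."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in LAMBDA_GRID])
    if m < 100:
        pi0 = 1.0
    else:
        pi0 = _smooth_pi0(LAMBDA_GRID, pi0_lambda, smoother)
        pi0 = min(max(pi0, 1.0 / m), 1.0)  # clip into (0, 1]
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(q=q, pi0=float(pi0), lambdas=LAMBDA_GRID.copy(), pi0_lambda=pi0_lambda)
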