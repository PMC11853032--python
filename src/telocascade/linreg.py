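"""Shared linear-regression results used by the screen and association modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LRResult", "fit_simple_lr", "ols_inference"]


@dataclass(frozen=True)
class LRResult:
    """A single regression coefficient with its Wald-style inference.

    ``slope`` is the coefficient B, (``ci_low``, ``ci_high``) its 95% CI from
    the t distribution, ``p_value`` the two-sided p, ``n`` the observations
    used.  A perfect (zero-residual) fit yields p = 0, which callers treat as a
    0-limit flag; B-H pooling floors it at machine epsilon.
    """

    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    stderr: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.slope) and not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must bracket the coefficient")


def fit_simple_lr(x, y, alpha: float = 0.05) -> LRResult:
    """Univariate ordinary least squares of y on x.

    Returns the slope with a t-based two-sided p and a (1−alpha) CI using
    df = n − 2.  Requires at least 3 complete pairs and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete (x, y) pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    df = n - 2
    tq = stats.t.ppf(1 - alpha / 2, df)
    se = float(res.stderr)
    p = float(res.pvalue)
    if se == 0 or not np.isfinite(p):  # perfect fit: zero residual variance
        p = 0.0
    return LRResult(
        slope=float(res.slope),
        ci_low=float(res.slope - tq * se),
        ci_high=float(res.slope + tq * se),
        p_value=p,
        n=n,
        stderr=se,
    )


def ols_inference(X: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Full-design OLS via least squares with classical t inference.

    Returns (coefs, stderrs, p_values, ci_low, ci_high, df_resid, rss).
    Raises on rank-deficient designs, reporting the condition number.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        cond = np.linalg.cond(X)
        raise ValueError(f"rank-deficient design (rank {rank} < {k}, condition number {cond:.3g})")
    coefs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    df = n - k
    rss = float(resid @ resid)
    # residuals at numerical-noise level are an exact fit: each coefficient is
    # then either truly 0 (p=1) or a 0-limit (p=0), never a ratio of rounding
    tol = 1e-10 * (1.0 + float(np.max(np.abs(y))))
    if rss <= n * tol ** 2:
        zero = np.abs(coefs) <= tol
        se = np.zeros(k)
        pvals = np.where(zero, 1.0, 0.0)
        coefs = np.where(zero, 0.0, coefs)
        return coefs, se, pvals, coefs.copy(), coefs.copy(), df, rss
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coefs / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    pvals = np.where(se > 0, pvals, np.where(np.abs(coefs) <= tol, 1.0, 0.0))
    tq = stats.t.ppf(1 - alpha / 2, df)
    return coefs, se, pvals, coefs - tq * se, coefs + tq * se, df, rss
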