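"""Trend, regression, significance-tier and weighted-KDE statistics."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import RegressionResult, TrendResult


def mann_kendall(values: Sequence[float]) -> tuple[int, float, float]:
    """Two-sided Mann–Kendall test with tie correction.

    Returns (S, z, p). A series with zero variance in S (all ties) gives
    z = 0 and p = 1.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(y[i + 1 :] - y[i])))
    _, counts = np.unique(y, return_counts=True)
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    var_s -= float(np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var_s <= 0:
        return s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, z, min(p, 1.0)


def theil_sen(years: Sequence[float], values: Sequence[float]) -> TrendResult:
    """Theil–Sen trend: median pairwise slope, with a Mann–Kendall p-value.

    The intercept is ``median(y - slope * x)``. Requires n >= 2 distinct
    x values; a constant series yields slope 0 and p = 1.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("years and values must have the same length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        raise ValueError("all years are equal; slope undefined")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    _, _, p = mann_kendall(y[np.argsort(x, kind="stable")])
    return TrendResult(slope=float(slope), intercept=float(intercept), p_value=p, n=len(x))


def ols_binned(x_totals: Sequence[float], y_totals: Sequence[float]) -> RegressionResult:
    """OLS with intercept on binned (per-year or per-year-per-ecoregion) sums.

    Reports the adjusted R²  ``1 - (1 - R²)(n - 1)/(n - 2)`` and the slope
    p-value. Requires n >= 3 and non-degenerate x.
    """
    x = np.asarray(x_totals, dtype=float)
    y = np.asarray(y_totals, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least three bins")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_adj=float(r2_adj),
        p_value=float(res.pvalue),
        n=n,
    )


def significance_tier(p: float) -> str:
    """Label a p-value: highly (<1e-4), moderately (<0.01), weakly (<0.05)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0001:
        return "highly"
    if p < 0.01:
        return "moderately"
    if p < 0.05:
        return "weakly"
    return "not significant"


def silverman_bandwidth(coords: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule on a weighted sample, using the effective sample size."""
    w = weights / weights.sum()
    mu = float(np.sum(w * coords))
    var = float(np.sum(w * (coords - mu) ** 2))
    n_eff = weights.sum() ** 2 / np.sum(weights**2)
    sd = math.sqrt(var)
    if sd == 0:
        return 1.0  # degenerate sample; any positive width works
    return 1.06 * sd * n_eff ** (-0.2)


def weighted_kde(
    coordinates: Sequence[float],
    weights: Sequence[float],
    bandwidth: Optional[float] = None,
    grid: Optional[np.ndarray] = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Gaussian kernel density on a 1-D grid.

    density(g) = Σ_i w_i N(g; x_i, h²) / Σ_i w_i. Bandwidth defaults to
    Silverman's rule on the weighted sample. Returns (grid, density); the
    trapezoid integral over the default grid is 1 within 1e-3.
    """
    x = np.asarray(coordinates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(x) != len(w):
        raise ValueError("coordinates and weights must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x, w)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min() - 5 * h, x.max() + 5 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ w / (w.sum() * h * math.sqrt(2 * math.pi))
    return grid, dens
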