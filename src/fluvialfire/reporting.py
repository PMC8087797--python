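"""Combine within-burn and downstream-propagated lengths into network-wide
percentages with bootstrap uncertainty."""

from __future__ import annotations

import importlib.metadata
import logging
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from .propagation import DEFAULT_IMPACT_THRESHOLD, solve_extent
from .types import DecayFit, UpscaledSummary

logger = logging.getLogger(__name__)


def upscale(
    summary: pd.DataFrame,
    multiplier: float = 1.0,
    multiplier_ci: Optional[tuple[float, float]] = None,
) -> UpscaledSummary:
    """Add the propagated length to the within-burn length per ecoregion.

    ``summary`` needs columns ``ecoregion``, ``sl_ba_km`` and
    ``network_km`` (total stream length per ecoregion). Under the default
    multiplier of 1 the propagated length equals the within-burn length,
    so the combined total is exactly twice SL_BA. Percentages are capped
    at 100 (and logged when capping occurs).
    """
    required = {"ecoregion", "sl_ba_km", "network_km"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary is missing columns: {sorted(missing)}")
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    t = summary.copy()
    t["sl_le_km"] = multiplier * t["sl_ba_km"]
    t["total_km"] = t["sl_ba_km"] + t["sl_le_km"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * t["total_km"] / t["network_km"]
    if (pct > 100).any():
        logger.warning("combined length exceeds network length; capping at 100%%")
    t["pct_of_network"] = np.clip(pct, 0.0, 100.0)

    m_lo, m_hi = multiplier_ci if multiplier_ci is not None else (multiplier, multiplier)
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = 100.0 * t["sl_ba_km"] * (1.0 + m_lo) / t["network_km"]
        hi = 100.0 * t["sl_ba_km"] * (1.0 + m_hi) / t["network_km"]
    t["ci95_low"] = np.clip(np.minimum(lo, t["pct_of_network"]), 0.0, 100.0)
    t["ci95_high"] = np.clip(np.maximum(hi, t["pct_of_network"]), 0.0, 100.0)

    total_ba = float(t["sl_ba_km"].sum())
    total_combined = float(t["total_km"].sum())
    net = float(t["network_km"].sum())
    pct_all = 100.0 * total_combined / net if net > 0 else float("nan")
    ci_all = (
        min(100.0, 100.0 * total_ba * (1.0 + m_lo) / net) if net > 0 else float("nan"),
        min(100.0, 100.0 * total_ba * (1.0 + m_hi) / net) if net > 0 else float("nan"),
    )
    return UpscaledSummary(
        table=t,
        total_sl_ba_km=total_ba,
        total_combined_km=total_combined,
        pct_of_network=min(100.0, pct_all) if net > 0 else pct_all,
        ci95=ci_all,
    )


def upscale_ci(
    fit: DecayFit,
    threshold: float = DEFAULT_IMPACT_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI on the SL_LE : SL_BA multiplier by parametric bootstrap.

    Draws fit parameters from a multivariate normal centred on the point
    estimate with the fit covariance (clipped at 0), re-solves the
    threshold crossing for each draw, and returns the 2.5/97.5 percentile
    band of the extent ratio relative to the point-estimate extent. Zero
    covariance yields a zero-width interval; identical seeds yield
    identical intervals.
    """
    if fit.cov is None:
        raise ValueError("fit has no covariance; cannot bootstrap")
    point = solve_extent(fit, threshold)
    if point <= 0:
        raise ValueError("point-estimate extent is zero; multiplier undefined")
    cov = np.asarray(fit.cov, dtype=float)
    theta = np.array([fit.a1, fit.k1, fit.a2, fit.k2])
    if not np.any(cov):
        return (1.0, 1.0)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta, cov, size=n_boot, method="svd")
    draws = np.clip(draws, 0.0, None)
    ratios = np.empty(n_boot)
    for i, (a1, k1, a2, k2) in enumerate(draws):
        f = DecayFit(
            a1=a1, k1=k1, a2=a2, k2=k2, r_squared=fit.r_squared,
            n_points=fit.n_points, degenerate=max(k1, k2) <= 1e-12,
        )
        if f.degenerate or f.delta0 <= threshold:
            ratios[i] = 0.0
            continue
        try:
            ratios[i] = solve_extent(f, threshold) / point
        except ValueError:
            # a zero-rate draw never decays below the threshold
            ratios[i] = np.inf
    ratios = np.minimum(ratios, 1e9)  # keep percentiles finite
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return (float(lo), float(hi))


def _frame(df: Optional[pd.DataFrame]):
    return df.to_dict(orient="records") if df is not None else None


def report(
    annual: Optional[pd.DataFrame] = None,
    upscaled: Optional[UpscaledSummary] = None,
    trend=None,
    regression=None,
    prop=None,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict:
    """Machine-readable summary of a pipeline run.

    All sections are optional; an empty call returns a valid, empty
    report. The config and seed are echoed for provenance.
    """
    try:
        version = importlib.metadata.version("fluvialfire")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    out = {
        "version": version,
        "seed": seed,
        "config": config or {},
        "annual_summary": _frame(annual),
        "upscaled": None,
        "trend": asdict(trend) if trend is not None else None,
        "regression": asdict(regression) if regression is not None else None,
        "propagation": asdict(prop) if prop is not None else None,
    }
    if upscaled is not None:
        out["upscaled"] = {
            "table": _frame(upscaled.table),
            "total_sl_ba_km": upscaled.total_sl_ba_km,
            "total_combined_km": upscaled.total_combined_km,
            "pct_of_network": upscaled.pct_of_network,
            "ci95": list(upscaled.ci95),
        }
    return out


def render_text(rep: dict) -> str:
    """Short human-readable rendering of :func:`report` output."""
    lines = [f"fluvialfire report (version {rep.get('version')}, seed {rep.get('seed')})"]
    up = rep.get("upscaled")
    if up:
        lines.append(
            f"  within-burn length: {up['total_sl_ba_km']:.1f} km; "
            f"combined with downstream extent: {up['total_combined_km']:.1f} km"
        )
        lines.append(f"  percent of network impacted: {up['pct_of_network']:.1f}%")
    tr = rep.get("trend")
    if tr:
        lines.append(f"  trend: {tr['slope']:.2f} km/year (p={tr['p_value']:.3g})")
    pr = rep.get("propagation")
    if pr:
        lines.append(
            f"  downstream extent: {pr['sl_le_km']:.1f} km "
            f"(threshold {pr['threshold_mgl']} mg/L, reaches order {pr['reached_order']})"
        )
    if len(lines) == 1:
        lines.append("  (empty run)")
    return "\n".join(lines)
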