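"""Downstream extent of water-quality disturbance.

Detects multi-station dissolved-oxygen sags, fits the biexponential decay
of sag magnitude with downstream distance, solves for the impact-threshold
crossing, and cross-checks the extent against the Horton stream-length
model (a geometric series over stream orders).
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks

from .types import DecayFit, HortonParams, PropagationEstimate, SagEvent, SondeSeries

logger = logging.getLogger(__name__)

#: Local aquatic-life dissolved-oxygen standard (mg/L).
DEFAULT_EXCEEDANCE_STANDARD = 5.4

#: Sag-depth threshold defining the end of the impacted reach (mg/L).
DEFAULT_IMPACT_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# sag detection


def sag_magnitude(
    series: SondeSeries,
    window: tuple,
    baseline_window_h: float = 24.0,
    event_id: int = 0,
    exceedance_standard: float = DEFAULT_EXCEEDANCE_STANDARD,
) -> SagEvent:
    """Sag at one station: pre-event baseline minus the within-window minimum.

    The baseline is the median DO over the ``baseline_window_h`` hours
    preceding the window.
    """
    t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    in_win = (series.times >= t0) & (series.times <= t1)
    if not in_win.any():
        raise ValueError("event window contains no samples")
    pre = (series.times >= t0 - pd.Timedelta(hours=baseline_window_h)) & (
        series.times < t0
    )
    if not pre.any():
        raise ValueError("no samples in the pre-event baseline window")
    baseline = float(np.median(series.do_mgl[pre]))
    win_do = series.do_mgl[in_win]
    win_t = series.times[in_win]
    i_min = int(np.argmin(win_do))
    min_do = float(win_do[i_min])
    delta = max(0.0, baseline - min_do)
    return SagEvent(
        event_id=event_id,
        station_id=series.station_id,
        distance_km=series.distance_km,
        baseline_do=baseline,
        min_do=min_do,
        delta_do=delta,
        t_min=win_t[i_min],
        below_standard=min_do < exceedance_standard,
    )


def _smooth(do: np.ndarray, times: pd.DatetimeIndex, smooth_h: float) -> np.ndarray:
    if smooth_h <= 0 or len(times) < 3:
        return do
    dt_h = np.median(np.diff(times.values).astype("timedelta64[s]").astype(float)) / 3600.0
    k = max(1, int(round(smooth_h / max(dt_h, 1e-9))))
    if k <= 1:
        return do
    if k % 2 == 0:
        k += 1
    return (
        pd.Series(do).rolling(k, center=True, min_periods=1).mean().to_numpy()
    )


def detect_sag_events(
    series: Sequence[SondeSeries],
    min_stations: int = 3,
    exceedance_standard: float = DEFAULT_EXCEEDANCE_STANDARD,
    prominence: float = 0.5,
    baseline_window_h: float = 24.0,
    window_h: float = 12.0,
    max_lag_h: float = 72.0,
    smooth_h: float = 1.0,
) -> list[list[SagEvent]]:
    """Group per-station DO sags into downstream-propagating events.

    Candidate minima are found per station on a lightly smoothed series
    (prominence threshold); candidates are chained across stations in
    distance order with strictly increasing minimum times within
    ``max_lag_h`` per hop. Chains shorter than ``min_stations`` are
    discarded; overlapping chains are merged by candidate consumption and
    logged. Each sag is flagged when its minimum falls below the
    exceedance standard.
    """
    if len(series) < min_stations:
        raise ValueError(f"need at least {min_stations} series")
    ordered = sorted(series, key=lambda s: s.distance_km)
    candidates: list[list[pd.Timestamp]] = []
    for s in ordered:
        sm = _smooth(s.do_mgl, s.times, smooth_h)
        idx, _ = find_peaks(-sm, prominence=prominence)
        candidates.append([s.times[i] for i in idx])

    used = [set() for _ in ordered]
    events: list[list[SagEvent]] = []
    event_id = 0
    while True:
        # globally earliest unused candidate seeds the next chain
        seed: Optional[tuple[int, int]] = None
        for si, cands in enumerate(candidates):
            for ci, t in enumerate(cands):
                if ci in used[si] and seed is not None:
                    continue
                if ci not in used[si] and (
                    seed is None or t < candidates[seed[0]][seed[1]]
                ):
                    seed = (si, ci)
        if seed is None:
            break
        si0, ci0 = seed
        chain = [(si0, ci0)]
        used[si0].add(ci0)
        prev_t = candidates[si0][ci0]
        for si in range(si0 + 1, len(ordered)):
            best = None
            for ci, t in enumerate(candidates[si]):
                if ci in used[si]:
                    continue
                if t > prev_t and (t - prev_t) <= pd.Timedelta(hours=max_lag_h):
                    if best is None or t < candidates[si][best]:
                        best = ci
            if best is None:
                continue
            chain.append((si, best))
            used[si].add(best)
            prev_t = candidates[si][best]
        if len(chain) < min_stations:
            logger.debug("discarding chain of %d station(s)", len(chain))
            continue
        sags = []
        last_t = None
        for si, ci in chain:
            tc = candidates[si][ci]
            sag = sag_magnitude(
                ordered[si],
                (tc - pd.Timedelta(hours=window_h), tc + pd.Timedelta(hours=window_h)),
                baseline_window_h=baseline_window_h,
                event_id=event_id,
                exceedance_standard=exceedance_standard,
            )
            if last_t is not None and sag.t_min <= last_t:
                logger.debug("dropping non-monotone sag at %s", sag.station_id)
                continue
            sags.append(sag)
            last_t = sag.t_min
        if len(sags) >= min_stations:
            events.append(sags)
            event_id += 1
    return events


# ---------------------------------------------------------------------------
# decay model


def _biexp(x, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * x) + a2 * np.exp(-k2 * x)


def _single_exp(x, a1, k1):
    return a1 * np.exp(-k1 * x)


def fit_decay(
    points: Sequence[tuple[float, float]],
    model: str = "biexponential",
) -> DecayFit:
    """Nonlinear least squares of sag magnitude vs downstream distance.

    Fits ``a1*exp(-k1*x) + a2*exp(-k2*x)`` (or a single exponential when
    ``model="single"``) with non-negativity bounds and multi-start
    initialisation; the best start by residual sum of squares wins.
    An all-equal input is returned as a degenerate zero-rate fit.
    """
    if model not in ("biexponential", "single"):
        raise ValueError("model must be 'biexponential' or 'single'")
    pts = np.asarray(points, dtype=float)
    min_n = 5 if model == "biexponential" else 3
    if pts.ndim != 2 or pts.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} (distance, delta) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("distances must span a positive range")

    if np.ptp(y) == 0:
        c = float(y[0])
        return DecayFit(
            a1=c, k1=0.0, a2=0.0, k2=0.0, r_squared=1.0, n_points=len(x),
            cov=np.zeros((4, 4)), degenerate=True, model=model,
        )

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    y0, yn = max(ys[0], 1e-12), max(ys[-1], 1e-12)
    kg = math.log(y0 / yn) / (xs[-1] - xs[0])
    kg = kg if kg > 0 else 0.01
    amp = float(ys[0] * math.exp(kg * xs[0]))

    if model == "single":
        starts = [(amp, kg), (amp, 2 * kg), (amp, 0.5 * kg), (max(ys), 0.01)]
        fn, npar = _single_exp, 2
    else:
        starts = [
            (0.999 * amp, kg, 0.001 * amp, 0.1 * kg),
            (0.7 * amp, 2.0 * kg, 0.3 * amp, kg / 3.0),
            (0.5 * amp, 1.5 * kg, 0.5 * amp, 0.5 * kg),
            (amp, 0.05, 0.1 * amp, 0.005),
            (amp, 0.01, 0.1 * amp, 0.001),
        ]
        fn, npar = _biexp, 4

    best = None
    failures = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                fn, x, y, p0=p0, bounds=(0.0, np.inf), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            failures.append(str(exc))
            continue
        ssr = float(np.sum((y - fn(x, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(f"decay fit failed for all starts: {failures}")
    ssr, popt, pcov = best
    if model == "biexponential" and not np.all(np.isfinite(pcov)):
        # second component unidentifiable (amplitude at the zero bound or
        # equal rates): the supported model is a single exponential
        logger.info("biexponential covariance singular; refitting single model")
        return fit_decay(points, model="single")
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    if model == "single":
        a1, k1 = popt
        a2 = k2 = 0.0
        cov = np.zeros((4, 4))
        cov[:2, :2] = pcov
    else:
        a1, k1, a2, k2 = popt
        cov = pcov
    return DecayFit(
        a1=float(a1), k1=float(k1), a2=float(a2), k2=float(k2),
        r_squared=r2, n_points=len(x), cov=cov,
        degenerate=bool(max(k1, k2) <= 1e-12), model=model,
    )


def solve_extent(fit: DecayFit, threshold: float = DEFAULT_IMPACT_THRESHOLD) -> float:
    """Distance (km) at which the fitted sag magnitude crosses the threshold.

    The biexponential with non-negative amplitudes and positive rates is
    strictly decreasing, so the root is unique; it is bracketed by
    doubling and solved to 1e-6 km. Returns 0 when the fitted magnitude
    never exceeds the threshold at the source.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if fit.delta0 <= threshold:
        logger.info("fitted magnitude at source <= threshold; extent 0")
        return 0.0
    if fit.degenerate:
        raise ValueError("degenerate (zero-rate) fit never crosses the threshold")
    asymptote = (fit.a1 if fit.k1 <= 0 else 0.0) + (fit.a2 if fit.k2 <= 0 else 0.0)
    if asymptote >= threshold:
        raise ValueError("fit has a zero-rate component above the threshold")
    hi = 1.0
    while fit.predict(hi) > threshold:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(
                "threshold crossing beyond 1e12 km; fit decays too slowly"
            )
    return float(brentq(lambda x: fit.predict(x) - threshold, 0.0, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Horton stream-length model


def horton_sl_le(params: HortonParams, omega: int, omega0: int = 1) -> float:
    """Longitudinal extent through orders omega0..omega under Horton's length law.

    Geometric sum of mean stream lengths ``Σ_i L̄·r_l**(i-1)`` for
    i = omega0..omega, with ``params.mean_l1`` the mean length at the
    source order. The r_l = 1 limit returns the plain count times L̄.
    """
    if omega0 < 1 or omega < omega0:
        raise ValueError("need omega >= omega0 >= 1")
    l1, r = params.mean_l1, params.r_l
    if r == 1.0:
        return l1 * (omega - omega0 + 1)
    if omega0 == 1:
        return l1 * (r**omega - 1.0) / (r - 1.0)
    return l1 * sum(r ** (i - 1) for i in range(omega0, omega + 1))


def horton_invert(sl_le_km: float, params: HortonParams) -> int:
    """Stream order reached by a disturbance of the given longitudinal extent.

    Inverts the omega0 = 1 geometric sum and rounds the continuous
    solution to the nearest integer order.
    """
    l1, r = params.mean_l1, params.r_l
    if sl_le_km < l1:
        raise ValueError(f"extent {sl_le_km} km is below one first-order length")
    if r == 1.0:
        omega = sl_le_km / l1
    else:
        omega = math.log(1.0 + sl_le_km * (r - 1.0) / l1, r)
    return max(1, int(round(omega)))


def estimate_propagation(
    fit: DecayFit,
    params: HortonParams,
    threshold: float = DEFAULT_IMPACT_THRESHOLD,
) -> PropagationEstimate:
    """Threshold-crossing extent plus the Horton order it corresponds to."""
    extent = solve_extent(fit, threshold)
    if extent < params.mean_l1:
        order = 1
    else:
        order = horton_invert(extent, params)
    return PropagationEstimate(
        sl_le_km=extent, threshold_mgl=threshold, reached_order=order
    )
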