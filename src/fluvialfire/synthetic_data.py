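"""Seeded synthetic inputs: Hortonian stream networks, burn scars,
ecoregion partitions, and multi-station dissolved-oxygen series.

Everything is generated on a planar Cartesian grid in kilometres so the
downstream geometry and statistics can be tested without external data.
All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd
from shapely.affinity import scale as shapely_scale
from shapely.geometry import LineString, Polygon, box

from .network import strahler_orders
from .types import (
    BurnGenSpec,
    BurnScar,
    DOSagSpec,
    EcoregionMap,
    HortonParams,
    SondeSeries,
    StreamNetwork,
    StreamSegment,
)

logger = logging.getLogger(__name__)

_N_STEPS = 4  # vertices per stream polyline (excluding the mouth)


class EmbeddingError(RuntimeError):
    """Raised when a network cannot be embedded in the requested region."""


# ---------------------------------------------------------------------------
# stream network generator


def _tributary_count(params: HortonParams, rng: np.random.Generator) -> int:
    # A stream of order w forms where two order-(w-1) streams meet, so the
    # count is floored at 2; the Poisson mean follows the bifurcation ratio.
    if params.length_cv == 0:
        return max(2, int(round(params.r_b)))
    return max(2, int(rng.poisson(params.r_b)))


def _length_factor(params: HortonParams, rng: np.random.Generator) -> float:
    if params.length_cv == 0:
        return 1.0
    cv2 = params.length_cv**2
    # gamma with mean 1 and the requested coefficient of variation
    return float(rng.gamma(1.0 / cv2, cv2))


def _abstract_tree(params: HortonParams, rng: np.random.Generator):
    """Stream records (id, order, length, parent, side index) without geometry."""
    streams = [
        {
            "id": "S0001",
            "order": params.max_order,
            "length": params.mean_length(params.max_order) * _length_factor(params, rng),
            "parent": None,
            "slot": 0,
        }
    ]
    counter = 1
    frontier = [streams[0]]
    while frontier:
        nxt = []
        for parent in frontier:
            if parent["order"] == 1:
                continue
            n_trib = _tributary_count(params, rng)
            for j in range(n_trib):
                counter += 1
                child = {
                    "id": f"S{counter:04d}",
                    "order": parent["order"] - 1,
                    "length": params.mean_length(parent["order"] - 1)
                    * _length_factor(params, rng),
                    "parent": parent["id"],
                    "slot": j,  # 0, 1 = formative pair at the head; rest are side tributaries
                }
                streams.append(child)
                nxt.append(child)
        frontier = nxt
    return streams


def _polyline(start, bearing, length, jitter_sd, rng) -> np.ndarray:
    """Piecewise-linear path of exact total length, mouth-first."""
    pts = [np.asarray(start, dtype=float)]
    step = length / _N_STEPS
    for _ in range(_N_STEPS):
        b = bearing if jitter_sd == 0 else bearing + rng.normal(0.0, jitter_sd)
        pts.append(pts[-1] + step * np.array([math.cos(b), math.sin(b)]))
    return np.array(pts)


_FORMATIVE_OFFSETS = (0.45, 0.65, 0.3, 0.85, 1.05, 0.2, 1.25)
_SIDE_OFFSETS = (1.1, 0.9, 1.3, 0.7, 1.5, 0.55)


def _candidate_ok(cand: np.ndarray, attach, placed: list, region) -> bool:
    """Candidate polyline must stay in the region and touch existing geometry
    only at its own mouth point."""
    xmin, ymin, xmax, ymax = region
    if (
        cand[:, 0].min() < xmin
        or cand[:, 0].max() > xmax
        or cand[:, 1].min() < ymin
        or cand[:, 1].max() > ymax
    ):
        return False
    g = LineString(cand)
    gb = g.bounds
    for other, ob in placed:
        if gb[2] < ob[0] or ob[2] < gb[0] or gb[3] < ob[1] or ob[3] < gb[1]:
            continue
        inter = g.intersection(other)
        if inter.is_empty:
            continue
        if inter.geom_type != "Point":
            return False
        if math.hypot(inter.x - attach[0], inter.y - attach[1]) > 1e-9:
            return False
    return True


class _Abort(Exception):
    """Internal: embedding attempt exceeded its operation budget."""


def _embed_once(streams, params, region, rng, max_ops: int = 400000):
    """One embedding attempt by depth-first backtracking.

    Each stream is tried at a list of branch-angle candidates relative to
    its parent's bearing; a candidate is kept only if the whole subtree
    below it can be placed, otherwise the subtree is unwound and the next
    candidate is tried. Returns {id: coords} (mouth-first) or None. With
    length_cv = 0 the search is fully deterministic.
    """
    xmin, ymin, xmax, ymax = region
    jitter_sd = 0.0 if params.length_cv == 0 else 0.06
    mouth0 = np.array([0.5 * (xmin + xmax), ymin + 0.02 * (ymax - ymin)])
    geom: dict[str, np.ndarray] = {}
    placed: list = []  # (segment_id, LineString, bounds) in placement order
    by_parent: dict[Optional[str], list[dict]] = {}
    for s in streams:
        by_parent.setdefault(s["parent"], []).append(s)
    ops = 0

    def candidates(child, pline, pbear):
        head = pline[-1]
        interior = list(range(1, _N_STEPS))
        if child["slot"] < 2:
            sign = 1 if child["slot"] == 0 else -1
            offs = [sign * o for o in _FORMATIVE_OFFSETS]
            offs += [-sign * o for o in (0.55, 0.8)]
            return [(head, pbear + o) for o in offs]
        k = child["slot"] - 2
        vi = interior[k % len(interior)]
        sign = 1 if k % 2 == 0 else -1
        out = [(pline[vi], pbear + sign * o) for o in _SIDE_OFFSETS]
        for v in interior:
            if v != vi:
                out += [(pline[v], pbear - sign * o) for o in _SIDE_OFFSETS[:3]]
        return out

    def place(stream, attach, bearing) -> bool:
        nonlocal ops
        ops += 1
        if ops > max_ops:
            raise _Abort
        line = _polyline(
            attach,
            bearing + (rng.normal(0.0, 0.05) if jitter_sd else 0.0),
            stream["length"],
            jitter_sd,
            rng,
        )
        if not _candidate_ok(line, attach, [(g, b) for _, g, b in placed], region):
            return False
        mark = len(placed)
        g = LineString(line)
        geom[stream["id"]] = line
        placed.append((stream["id"], g, g.bounds))
        for child in by_parent.get(stream["id"], []):
            done = False
            for a, b in candidates(child, line, bearing):
                if place(child, a, b):
                    done = True
                    break
            if not done:
                for sid, _, _ in placed[mark:]:
                    geom.pop(sid, None)
                del placed[mark:]
                return False
        return True

    root = streams[0]
    try:
        ok = place(root, mouth0, math.pi / 2)
    except _Abort:
        return None
    return geom if ok else None


def generate_network(
    params: HortonParams,
    region: tuple[float, float, float, float],
    seed: int,
    max_attempts: int = 30,
) -> StreamNetwork:
    """Generate a tree-structured stream network obeying Horton's length law.

    Each order-w stream is one polyline segment whose expected length is
    ``mean_l1 * r_l**(w-1)``; every order-w stream (w >= 2) receives at
    least two order-(w-1) tributaries, so recomputed Strahler orders equal
    the generated ones. Geometry is piecewise-linear with small bearing
    jitter, rejection-sampled against self-intersection and region escape.

    Raises
    ------
    ValueError
        If the region is too small to embed the tree.
    EmbeddingError
        If no non-intersecting embedding is found within ``max_attempts``.
    """
    xmin, ymin, xmax, ymax = region
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("region must have positive extent")
    mainstem = sum(params.mean_length(w) for w in range(1, params.max_order + 1))
    mainstem *= 1.0 + 2.0 * params.length_cv
    if (ymax - ymin) < 1.1 * mainstem or (xmax - xmin) < 1.4 * mainstem:
        raise ValueError(
            f"region {region} too small to embed a {params.max_order}-order network "
            f"(needs roughly {1.4 * mainstem:.1f} km across); refusing to clip"
        )

    rng = np.random.default_rng(seed)
    geom = None
    for _ in range(max_attempts):
        # redraw the tree each attempt: occasional pathologically bushy trees
        # are rejection-sampled away along with bad jitter draws
        streams = _abstract_tree(params, rng)
        geom = _embed_once(streams, params, region, rng, max_ops=100000)
        if geom is not None:
            break
        if params.length_cv == 0:
            raise EmbeddingError(
                "deterministic embedding failed; enlarge the region"
            )
    if geom is None:
        raise EmbeddingError(f"no valid embedding after {max_attempts} attempts")

    segments = [
        StreamSegment(
            segment_id=s["id"],
            coords=geom[s["id"]][::-1],  # store source → mouth
            strahler_order=s["order"],
        )
        for s in streams
    ]
    topology = {s["id"]: s["parent"] for s in streams}
    net = StreamNetwork(segments=segments, topology=topology, region=region)
    recomputed = strahler_orders(topology)
    for s in streams:
        assert recomputed[s["id"]] == s["order"], "generator violated Strahler rule"
    return net


# ---------------------------------------------------------------------------
# burn scars


def _star_polygon(center, mean_radius, rng: Optional[np.random.Generator]) -> Polygon:
    n = 12
    base = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    if rng is None:
        ang, rad = base, np.full(n, mean_radius)
    else:
        ang = base + rng.uniform(0.05, 0.45, n) * (2.0 * math.pi / n)
        rad = mean_radius * rng.uniform(0.65, 1.35, n)
    xs = center[0] + rad * np.cos(ang)
    ys = center[1] + rad * np.sin(ang)
    return Polygon(zip(xs, ys))


def _slice_by_fractions(poly: Polygon, parts: list[tuple[str, float]]):
    """Partition a polygon into vertical strips with exact area fractions."""
    xmin, ymin, xmax, ymax = poly.bounds
    pad = 1.0
    total = poly.area

    def area_left(x: float) -> float:
        return poly.intersection(box(xmin - pad, ymin - pad, x, ymax + pad)).area

    patches = []
    cum = 0.0
    x_prev = xmin - pad
    for idx, (cls, frac) in enumerate(parts):
        cum += frac
        if idx == len(parts) - 1:
            x_cut = xmax + pad
        else:
            target = cum * total
            lo, hi = xmin, xmax
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if area_left(mid) < target:
                    lo = mid
                else:
                    hi = mid
            x_cut = 0.5 * (lo + hi)
        patch = poly.intersection(box(x_prev, ymin - pad, x_cut, ymax + pad))
        patches.append((cls, patch))
        x_prev = x_cut
    return patches


def generate_burn_scars(
    region: tuple[float, float, float, float],
    spec: BurnGenSpec,
    seed: int,
) -> list[BurnScar]:
    """Generate lognormally sized burn scars with severity-class patches.

    Each scar perimeter is a simple star-shaped polygon scaled to its drawn
    area; severity patches are vertical slices whose areas match
    ``spec.severity_fractions`` exactly (so per-class fractions hold for
    every scar, not just in the limit).
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region
    parts = [(c, f) for c, f in sorted(spec.severity_fractions.items()) if f > 0]
    scars = []
    for i in range(spec.n_fires):
        area = float(rng.lognormal(spec.area_log_mean, spec.area_log_sd))
        r0 = math.sqrt(area / math.pi)
        lo_x, hi_x = xmin + 1.5 * r0, xmax - 1.5 * r0
        lo_y, hi_y = ymin + 1.5 * r0, ymax - 1.5 * r0
        cx = rng.uniform(lo_x, hi_x) if lo_x < hi_x else 0.5 * (xmin + xmax)
        cy = rng.uniform(lo_y, hi_y) if lo_y < hi_y else 0.5 * (ymin + ymax)
        poly = _star_polygon((cx, cy), r0, rng)
        poly = shapely_scale(poly, *(math.sqrt(area / poly.area),) * 2, origin="centroid")
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        patches = _slice_by_fractions(poly, parts)
        scars.append(
            BurnScar(
                fire_id=f"F{i + 1:04d}",
                year=year,
                perimeter=poly,
                severity_patches=patches,
            )
        )
    return scars


# ---------------------------------------------------------------------------
# ecoregions


def generate_ecoregions(
    region: tuple[float, float, float, float],
    n_regions: int,
    seed: int,
) -> EcoregionMap:
    """Partition the region box into ``n_regions`` rectangular ecoregions.

    Column widths and row heights are Dirichlet-random, so region areas
    vary while the union tiles the box exactly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region
    ncols = math.ceil(math.sqrt(n_regions))
    base = n_regions // ncols
    extra = n_regions % ncols
    rows_per_col = [base + (1 if c < extra else 0) for c in range(ncols)]
    rows_per_col = [r for r in rows_per_col if r > 0]
    ncols = len(rows_per_col)

    widths = rng.dirichlet(4.0 * np.ones(ncols)) * (xmax - xmin)
    xs = np.concatenate([[xmin], xmin + np.cumsum(widths)])
    xs[-1] = xmax
    regions: dict[str, Polygon] = {}
    k = 0
    for c, nrows in enumerate(rows_per_col):
        heights = rng.dirichlet(4.0 * np.ones(nrows)) * (ymax - ymin)
        ys = np.concatenate([[ymin], ymin + np.cumsum(heights)])
        ys[-1] = ymax
        for r in range(nrows):
            k += 1
            regions[f"E{k:02d}"] = box(xs[c], ys[r], xs[c + 1], ys[r + 1])
    return EcoregionMap(regions=regions, region=region)


# ---------------------------------------------------------------------------
# dissolved-oxygen series


def generate_do_series(spec: DOSagSpec, seed: int) -> list[SondeSeries]:
    """Generate per-station DO series with Gaussian-shaped sags.

    At along-channel distance x each event produces a dip of depth
    ``a1*exp(-k1*x) + a2*exp(-k2*x)`` centred at the event time plus the
    travel lag ``x / celerity``; the exact centre instants are included in
    the sampling grid so that, at ``noise_sd = 0``, the series minimum
    equals baseline minus depth exactly. Values are clipped at 0 mg/L
    (anoxia) and clippings are logged.
    """
    rng = np.random.default_rng(seed)
    events = pd.to_datetime(list(spec.event_times))
    if len(events) == 0:
        raise ValueError("at least one event time required")
    distances = np.asarray(spec.station_distances, dtype=float)
    max_lag = pd.Timedelta(hours=float(distances.max()) / spec.celerity_kmh)
    t0 = events.min() - pd.Timedelta(days=3)
    t1 = events.max() + max_lag + pd.Timedelta(days=3)
    grid = pd.date_range(t0, t1, freq=pd.Timedelta(minutes=spec.sample_interval_min))

    sigma_h = spec.sag_sigma_h
    series = []
    for s_idx, x in enumerate(distances):
        depth = spec.depth_at(x)
        centers = pd.DatetimeIndex(
            [ev + pd.Timedelta(hours=x / spec.celerity_kmh) for ev in events]
        )
        times = grid.union(centers)
        th = (times - times[0]).total_seconds() / 3600.0
        do = np.full(len(times), spec.baseline_do, dtype=float)
        for c in centers:
            ch = (c - times[0]).total_seconds() / 3600.0
            do -= depth * np.exp(-0.5 * ((th - ch) / sigma_h) ** 2)
        if spec.noise_sd > 0:
            do += rng.normal(0.0, spec.noise_sd, len(do))
        n_clip = int(np.sum(do < 0))
        if n_clip:
            logger.warning(
                "station %d: clipped %d anoxic samples at 0 mg/L", s_idx + 1, n_clip
            )
            do = np.clip(do, 0.0, None)
        series.append(
            SondeSeries(
                station_id=f"S{s_idx + 1}",
                distance_km=float(x),
                times=times,
                do_mgl=do,
            )
        )
    return series
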