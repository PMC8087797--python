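"""Domain containers shared across the pipeline.

All coordinates are planar Cartesian kilometres; inputs in geographic
(degree) coordinates are out of scope and must be pre-projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

#: MTBS-style severity classes.
SEVERITY_CLASSES = (
    "unburned",
    "low",
    "moderate",
    "high",
    "increased_greenness",
    "masked",
)

#: Classes that count as burned when deriving the fire footprint.
RETAINED_CLASSES = ("low", "moderate", "high")


# ---------------------------------------------------------------------------
# stream network


@dataclass
class StreamSegment:
    """A single stream reach as an ordered planar polyline (km).

    Vertices run from the upstream source to the downstream mouth.
    """

    segment_id: str
    coords: np.ndarray
    strahler_order: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"segment {self.segment_id}: coords must be (n, 2)")
        if len(self.coords) < 2:
            raise ValueError(f"segment {self.segment_id}: needs >= 2 vertices")
        if self.length_km <= 0:
            raise ValueError(f"segment {self.segment_id}: zero-length polyline")

    @property
    def length_km(self) -> float:
        d = np.diff(self.coords, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class StreamNetwork:
    """A forest of stream segments with child-mouth-to-parent topology.

    ``topology`` maps a child's segment_id to its parent's segment_id;
    roots map to ``None``.
    """

    segments: list[StreamSegment]
    topology: dict[str, Optional[str]]
    region: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        ids = {s.segment_id for s in self.segments}
        if len(ids) != len(self.segments):
            raise ValueError("duplicate segment ids")
        for child, parent in self.topology.items():
            if child not in ids:
                raise ValueError(f"topology references unknown segment {child!r}")
            if parent is not None and parent not in ids:
                raise ValueError(f"unknown parent {parent!r} for {child!r}")
        self._assert_forest()

    def _assert_forest(self) -> None:
        for start in self.topology:
            seen = {start}
            node = self.topology.get(start)
            while node is not None:
                if node in seen:
                    raise ValueError("topology contains a cycle")
                seen.add(node)
                node = self.topology.get(node)

    @property
    def total_length_km(self) -> float:
        return float(sum(s.length_km for s in self.segments))

    @property
    def region_area_km2(self) -> Optional[float]:
        if self.region is None:
            return None
        xmin, ymin, xmax, ymax = self.region
        return (xmax - xmin) * (ymax - ymin)

    def children_map(self) -> dict[Optional[str], list[str]]:
        out: dict[Optional[str], list[str]] = {}
        for child, parent in self.topology.items():
            out.setdefault(parent, []).append(child)
        return out

    def segment(self, segment_id: str) -> StreamSegment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)


# ---------------------------------------------------------------------------
# burn scars and ecoregions


@dataclass
class BurnScar:
    """Fire perimeter with severity-class patches."""

    fire_id: str
    year: int
    perimeter: Polygon
    severity_patches: list[tuple[str, BaseGeometry]]

    def __post_init__(self) -> None:
        for cls, patch in self.severity_patches:
            if cls not in SEVERITY_CLASSES:
                raise ValueError(f"unknown severity class {cls!r}")
            outside = patch.difference(self.perimeter).area
            if self.perimeter.area > 0 and outside / self.perimeter.area > 1e-6:
                raise ValueError(
                    f"fire {self.fire_id}: patch {cls!r} extends outside perimeter"
                )


@dataclass
class EcoregionMap:
    """Named polygons partitioning the study region."""

    regions: dict[str, BaseGeometry]
    region: Optional[tuple[float, float, float, float]] = None

    @property
    def names(self) -> list[str]:
        return sorted(self.regions)

    def area_km2(self, name: str) -> float:
        return float(self.regions[name].area)


@dataclass
class FireImpactRecord:
    """Per-fire result: severity-filtered burned area and clipped stream length."""

    fire_id: str
    year: int
    ecoregion: str
    burned_area_km2: float
    sl_ba_km: float


# ---------------------------------------------------------------------------
# generator specs


@dataclass
class HortonParams:
    """Parameters of the Hortonian network generator and length-law model.

    ``mean_l1`` is the mean first-order stream length; order-w streams
    average ``mean_l1 * r_l**(w - 1)``.
    """

    r_b: float = 2.0
    r_l: float = 2.0
    mean_l1: float = 1.3
    max_order: int = 4
    length_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.r_b <= 1:
            raise ValueError("r_b must exceed 1")
        if self.r_l <= 0:
            raise ValueError("r_l must be positive")
        if self.mean_l1 <= 0:
            raise ValueError("mean_l1 must be positive")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.length_cv < 0:
            raise ValueError("length_cv must be >= 0")

    def mean_length(self, order: int) -> float:
        return self.mean_l1 * self.r_l ** (order - 1)


@dataclass
class BurnGenSpec:
    """Lognormal fire sizes with fixed severity-class proportions."""

    n_fires: int
    area_log_mean: float
    area_log_sd: float
    severity_fractions: dict[str, float]
    year_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_fires < 0:
            raise ValueError("n_fires must be >= 0")
        if self.area_log_sd < 0:
            raise ValueError("area_log_sd must be >= 0")
        unknown = set(self.severity_fractions) - set(SEVERITY_CLASSES)
        if unknown:
            raise ValueError(f"unknown severity classes: {sorted(unknown)}")
        if any(v < 0 for v in self.severity_fractions.values()):
            raise ValueError("severity fractions must be >= 0")
        total = sum(self.severity_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity fractions sum to {total}, expected 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")


@dataclass
class DOSagSpec:
    """Multi-station dissolved-oxygen series with exponentially decaying sags.

    Sag depth at along-channel distance x is
    ``a1*exp(-k1*x) + a2*exp(-k2*x)``; arrival lags are ``x / celerity``.
    """

    station_distances: Sequence[float]
    baseline_do: float
    components: tuple[float, float, float, float]
    event_times: Sequence
    noise_sd: float = 0.0
    sample_interval_min: float = 15.0
    celerity_kmh: float = 4.0
    sag_sigma_h: float = 2.0

    def __post_init__(self) -> None:
        d = np.asarray(self.station_distances, dtype=float)
        if len(d) == 0 or np.any(np.diff(d) <= 0):
            raise ValueError("station_distances must be strictly increasing")
        a1, k1, a2, k2 = self.components
        if min(a1, k1, a2, k2) < 0:
            raise ValueError("decay components must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_interval_min <= 0 or self.celerity_kmh <= 0:
            raise ValueError("sample_interval_min and celerity_kmh must be > 0")

    def depth_at(self, x: float) -> float:
        a1, k1, a2, k2 = self.components
        return a1 * np.exp(-k1 * x) + a2 * np.exp(-k2 * x)


# ---------------------------------------------------------------------------
# sonde series, sag events, decay fits


@dataclass
class SondeSeries:
    """One station's dissolved-oxygen time series."""

    station_id: str
    distance_km: float
    times: pd.DatetimeIndex
    do_mgl: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.do_mgl = np.asarray(self.do_mgl, dtype=float)
        if len(self.times) != len(self.do_mgl):
            raise ValueError("times and do_mgl length mismatch")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.times.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.do_mgl < 0):
            raise ValueError("do_mgl must be >= 0")


@dataclass
class SagEvent:
    """A dissolved-oxygen sag at one station: baseline minus within-window minimum."""

    event_id: int
    station_id: str
    distance_km: float
    baseline_do: float
    min_do: float
    delta_do: float
    t_min: pd.Timestamp
    below_standard: bool = False


@dataclass
class DecayFit:
    """Biexponential fit of sag magnitude versus downstream distance."""

    a1: float
    k1: float
    a2: float
    k2: float
    r_squared: float
    n_points: int
    cov: Optional[np.ndarray] = None
    degenerate: bool = False
    model: str = "biexponential"

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a1 * np.exp(-self.k1 * x) + self.a2 * np.exp(-self.k2 * x)

    @property
    def delta0(self) -> float:
        return self.a1 + self.a2

    def components_sorted(self) -> list[tuple[float, float]]:
        """(amplitude, rate) pairs, largest amplitude first.

        Components whose rates agree within 0.1% are indistinguishable and
        are merged into one with the amplitude-weighted rate.
        """
        a_sum = self.a1 + self.a2
        if a_sum > 0 and abs(self.k1 - self.k2) <= 1e-3 * max(self.k1, self.k2):
            k_bar = (self.a1 * self.k1 + self.a2 * self.k2) / a_sum
            return [(a_sum, k_bar), (0.0, 0.0)]
        comps = [(self.a1, self.k1), (self.a2, self.k2)]
        return sorted(comps, key=lambda c: -c[0])


@dataclass
class PropagationEstimate:
    """Longitudinal disturbance extent and the stream order it reaches."""

    sl_le_km: float
    threshold_mgl: float
    reached_order: int


# ---------------------------------------------------------------------------
# statistics results


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n: int


@dataclass
class UpscaledSummary:
    """Per-ecoregion burned + propagated lengths and percent of network."""

    table: pd.DataFrame
    total_sl_ba_km: float = 0.0
    total_combined_km: float = 0.0
    pct_of_network: float = field(default=float("nan"))
    ci95: tuple[float, float] = (float("nan"), float("nan"))
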