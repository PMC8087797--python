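import numpy as np
import pandas as pd
import pytest
from shapely import contains_xy
from shapely.geometry import Polygon, box

from fluvialfire import sl_ba
from fluvialfire.types import BurnScar, EcoregionMap, FireImpactRecord, StreamNetwork, StreamSegment


def _scar(perimeter, patches, fire_id="F1", year=2000):
    return BurnScar(
        fire_id=fire_id, year=year, perimeter=perimeter, severity_patches=patches
    )


def _record(fire_id, area, year=2000, eco="E", slba=0.0):
    return FireImpactRecord(
        fire_id=fire_id, year=year, ecoregion=eco, burned_area_km2=area, sl_ba_km=slba
    )


class TestSeverityFilter:
    def test_all_high_equals_perimeter(self):
        sq = box(0, 0, 2, 2)
        fp = sl_ba.severity_filter(_scar(sq, [("high", sq)]))
        assert fp.area == pytest.approx(sq.area)

    def test_all_unburned_empty(self):
        sq = box(0, 0, 2, 2)
        fp = sl_ba.severity_filter(_scar(sq, [("unburned", sq)]))
        assert fp.area == 0.0

    def test_half_low_half_masked(self):
        sq = box(0, 0, 2, 2)
        left, right = box(0, 0, 1, 2), box(1, 0, 2, 2)
        fp = sl_ba.severity_filter(_scar(sq, [("low", left), ("masked", right)]))
        assert fp.area == pytest.approx(0.5 * sq.area)

    def test_idempotent(self):
        sq = box(0, 0, 2, 2)
        fp = sl_ba.severity_filter(_scar(sq, [("low", box(0, 0, 1, 2))]))
        again = sl_ba.severity_filter(_scar(sq, [("low", fp)]))
        assert again.area == pytest.approx(fp.area)


class TestMinAreaFilter:
    def test_basic(self):
        recs = [_record("a", 2.0), _record("b", 5.0), _record("c", 10.0)]
        kept = sl_ba.apply_min_area_filter(recs, 4.1)
        assert [r.burned_area_km2 for r in kept] == [5.0, 10.0]

    def test_boundary_retained(self):
        assert len(sl_ba.apply_min_area_filter([_record("a", 4.1)], 4.1)) == 1

    def test_empty(self):
        assert sl_ba.apply_min_area_filter([], 4.1) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sl_ba.apply_min_area_filter([], -1.0)

    def test_idempotent(self):
        recs = [_record("a", 2.0), _record("b", 5.0)]
        once = sl_ba.apply_min_area_filter(recs)
        assert sl_ba.apply_min_area_filter(once) == once


class TestClipLength:
    def test_disjoint_zero(self, network):
        far = box(1000, 1000, 1001, 1001)
        assert sl_ba.clip_length(network, far) == 0.0

    def test_analytic_unit_square(self):
        seg = StreamSegment("s", np.array([[-1.0, 0.5], [2.0, 0.5]]))
        net = StreamNetwork(segments=[seg], topology={"s": None})
        assert sl_ba.clip_length(net, box(0, 0, 1, 1)) == pytest.approx(1.0)

    def test_full_region_equals_total(self, network, region):
        full = box(*region)
        assert sl_ba.clip_length(network, full) == pytest.approx(
            network.total_length_km, rel=1e-9
        )

    def test_invalid_polygon_rejected(self, network):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="[Ii]nvalid|[Ss]elf"):
            sl_ba.clip_length(network, bowtie)

    def test_additive_over_disjoint_footprints(self, network):
        a, b = box(10, 10, 30, 30), box(40, 10, 60, 30)
        both = a.union(b)
        assert sl_ba.clip_length(network, both) == pytest.approx(
            sl_ba.clip_length(network, a) + sl_ba.clip_length(network, b), rel=1e-9
        )

    def test_monotone_under_superset(self, network):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x, y = rng.uniform(10, 60), rng.uniform(10, 35)
            small = box(x, y, x + 8, y + 8)
            big = small.buffer(3.0)
            assert sl_ba.clip_length(network, big) >= sl_ba.clip_length(network, small)

    def test_matches_dense_subdivision_oracle(self, network):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cx, cy = rng.uniform(15, 65), rng.uniform(12, 38)
            r = rng.uniform(5, 12)
            fp = box(cx - r, cy - r, cx + r, cy + r)
            exact = sl_ba.clip_length(network, fp)
            oracle = subdivision_oracle(network, fp, step_km=0.001)
            assert exact == pytest.approx(oracle, rel=1e-3)


def subdivision_oracle(network, footprint, step_km=0.001):
    """Brute force: chop every polyline into ~1 m steps and keep the steps
    whose midpoints fall inside the footprint."""
    total = 0.0
    for seg in network.segments:
        c = seg.coords
        for p, q in zip(c[:-1], c[1:]):
            d = float(np.hypot(*(q - p)))
            n = max(1, int(np.ceil(d / step_km)))
            t = (np.arange(n) + 0.5) / n
            mids = p[None, :] + t[:, None] * (q - p)[None, :]
            inside = contains_xy(footprint, mids[:, 0], mids[:, 1])
            total += inside.sum() * (d / n)
    return total


class TestAssignEcoregion:
    emap = EcoregionMap(regions={"E1": box(0, 0, 6, 10), "E2": box(6, 0, 10, 10)})

    def test_largest_area_wins(self):
        fp = box(2, 0, 8, 10)  # 4 units in E1, 2 in E2
        assert sl_ba.assign_ecoregion(fp, self.emap) == "E1"

    def test_wholly_inside(self):
        assert sl_ba.assign_ecoregion(box(1, 1, 2, 2), self.emap) == "E1"

    def test_exact_tie_breaks_lexicographically(self):
        emap = EcoregionMap(regions={"B": box(5, 0, 10, 10), "A": box(0, 0, 5, 10)})
        fp = box(4, 0, 6, 10)
        assert sl_ba.assign_ecoregion(fp, emap) == "A"

    def test_outside_all_is_unassigned(self):
        assert sl_ba.assign_ecoregion(box(100, 100, 101, 101), self.emap) == sl_ba.UNASSIGNED

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError):
            sl_ba.assign_ecoregion(box(0, 0, 1, 1).intersection(box(5, 5, 6, 6)), self.emap)


class TestMisattribution:
    emap = EcoregionMap(regions={"E1": box(0, 0, 6, 10), "E2": box(6, 0, 10, 10)})

    def test_wholly_within_gives_zero(self):
        sq = box(1, 1, 3, 3)
        scar = _scar(sq, [("high", sq)])
        recs = [_record("F1", sq.area, eco="E1")]
        fr = sl_ba.misattribution_fraction(recs, [scar], self.emap)
        assert fr == {"E1": 0.0, "E2": 0.0}

    def test_split_fire_misattributes_minor_region(self):
        fp = box(2, 0, 8, 10)  # 60% in E1 -> fire assigned to E1
        scar = _scar(fp, [("high", fp)])
        recs = [_record("F1", fp.area, eco="E1")]
        fr = sl_ba.misattribution_fraction(recs, [scar], self.emap)
        assert fr["E1"] == 0.0
        assert fr["E2"] == pytest.approx(1.0)

    def test_fractions_bounded(self, scars, ecoregions, network):
        recs = sl_ba.compute_fire_impacts(network, scars, ecoregions, threshold_km2=0.0)
        fr = sl_ba.misattribution_fraction(recs, scars, ecoregions)
        assert all(0.0 <= v <= 1.0 for v in fr.values())


class TestComputeFireImpacts:
    def test_no_scars(self, network, ecoregions):
        assert sl_ba.compute_fire_impacts(network, [], ecoregions) == []

    def test_region_covering_scar_captures_total_length(self, network, region, ecoregions):
        big = box(*region)
        scar = _scar(big, [("high", big)])
        (rec,) = sl_ba.compute_fire_impacts(network, [scar], ecoregions)
        assert rec.sl_ba_km == pytest.approx(network.total_length_km, rel=1e-9)

    def test_composition_matches_direct_clip(self, network, scars, ecoregions):
        recs = sl_ba.compute_fire_impacts(network, scars, ecoregions, threshold_km2=4.1)
        by_id = {s.fire_id: s for s in scars}
        for rec in recs:
            fp = sl_ba.severity_filter(by_id[rec.fire_id])
            assert rec.sl_ba_km == pytest.approx(sl_ba.clip_length(network, fp))

    def test_area_mode_switch(self, network, scars, ecoregions):
        filt = sl_ba.compute_fire_impacts(network, scars, ecoregions, threshold_km2=0.0)
        perim = sl_ba.compute_fire_impacts(
            network, scars, ecoregions, threshold_km2=0.0, area_mode="perimeter"
        )
        by_id = {s.fire_id: s.perimeter.area for s in scars}
        for rf, rp in zip(filt, perim):
            assert rp.burned_area_km2 == pytest.approx(by_id[rp.fire_id])
            assert rf.burned_area_km2 < rp.burned_area_km2  # severity classes removed

    def test_conservation_when_footprints_tile_region(self, network, region, ecoregions):
        xmin, ymin, xmax, ymax = region
        xs = np.linspace(xmin, xmax, 5)
        ys = np.linspace(ymin, ymax, 4)
        scars = []
        k = 0
        for x0, x1 in zip(xs[:-1], xs[1:]):
            for y0, y1 in zip(ys[:-1], ys[1:]):
                tile = box(x0, y0, x1, y1)
                scars.append(_scar(tile, [("high", tile)], fire_id=f"T{k}"))
                k += 1
        recs = sl_ba.compute_fire_impacts(network, scars, ecoregions, threshold_km2=0.0)
        assert sum(r.sl_ba_km for r in recs) == pytest.approx(
            network.total_length_km, rel=1e-6
        )


class TestAggregateAnnual:
    def test_single_record(self):
        t = sl_ba.aggregate_annual([_record("a", 5.0, year=1999, eco="E1", slba=2.0)])
        assert len(t) == 1
        row = t.iloc[0]
        assert (row.year, row.ecoregion, row.burned_area_km2, row.sl_ba_km) == (
            1999, "E1", 5.0, 2.0,
        )

    def test_conservation(self, network, scars, ecoregions):
        recs = sl_ba.compute_fire_impacts(network, scars, ecoregions)
        t = sl_ba.aggregate_annual(recs)
        assert t["sl_ba_km"].sum() == pytest.approx(sum(r.sl_ba_km for r in recs))
        assert t["burned_area_km2"].sum() == pytest.approx(
            sum(r.burned_area_km2 for r in recs)
        )

    def test_same_key_rows_summed(self):
        recs = [
            _record("a", 5.0, year=1999, eco="E1", slba=2.0),
            _record("b", 3.0, year=1999, eco="E1", slba=1.5),
        ]
        t = sl_ba.aggregate_annual(recs)
        assert len(t) == 1
        assert t.iloc[0].burned_area_km2 == pytest.approx(8.0)
        assert t.iloc[0].sl_ba_km == pytest.approx(3.5)

    def test_missing_combinations_flagged_zero(self):
        recs = [
            _record("a", 5.0, year=1999, eco="E1"),
            _record("b", 3.0, year=2000, eco="E2"),
        ]
        t = sl_ba.aggregate_annual(recs)
        assert len(t) == 4
        empty = t[(t.year == 1999) & (t.ecoregion == "E2")].iloc[0]
        assert empty.no_fires and empty.burned_area_km2 == 0.0


class TestDrainageRatioTable:
    def test_density_arithmetic(self):
        seg = StreamSegment("s", np.array([[0.0, 1.0], [10.0, 1.0]]))
        net = StreamNetwork(segments=[seg], topology={"s": None})
        # 10 x 0.5 box (area 5 km^2) containing the 10 km segment
        emap = EcoregionMap(regions={"E1": box(0, 0.75, 10, 1.25)})
        annual = pd.DataFrame(
            {"year": [2000], "ecoregion": ["E1"], "burned_area_km2": [1.0],
             "sl_ba_km": [1.0], "no_fires": [False]}
        )
        t = sl_ba.drainage_ratio_table(emap, net, annual)
        assert t.loc[0, "drainage_density"] == pytest.approx(2.0)

    def test_no_burned_area_is_missing(self, network, ecoregions):
        annual = pd.DataFrame(
            {"year": [2000], "ecoregion": ["E01"], "burned_area_km2": [0.0],
             "sl_ba_km": [0.0], "no_fires": [True]}
        )
        t = sl_ba.drainage_ratio_table(ecoregions, network, annual)
        assert np.isnan(t.set_index("ecoregion").loc["E01", "slba_burned_ratio"])

    def test_uniform_sampling_ratio_approaches_density(self, network, region):
        # footprints tiling the region exactly reproduce density as the ratio
        xmin, ymin, xmax, ymax = region
        emap_one = EcoregionMap(regions={"ALL": box(*region)})
        xs = np.linspace(xmin, xmax, 7)
        ys = np.linspace(ymin, ymax, 5)
        scars = []
        k = 0
        for x0, x1 in zip(xs[:-1], xs[1:]):
            for y0, y1 in zip(ys[:-1], ys[1:]):
                tile = box(x0, y0, x1, y1)
                scars.append(_scar(tile, [("high", tile)], fire_id=f"T{k}"))
                k += 1
        recs = sl_ba.compute_fire_impacts(network, scars, emap_one, threshold_km2=0.0)
        annual = sl_ba.aggregate_annual(recs)
        t = sl_ba.drainage_ratio_table(emap_one, network, annual)
        density = t.loc[0, "drainage_density"]
        ratio = t.loc[0, "slba_burned_ratio"]
        assert ratio == pytest.approx(density, rel=1e-6)
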