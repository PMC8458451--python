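import numpy as np
import pytest

from sounderspace import overlap as ov
from sounderspace.overlap import (
    Dyad,
    OverlapRecord,
    aggregate_by_sow,
    extract_isopleth,
    find_dyads,
    overlap_2d,
    volume_of_intersection,
)

from conftest import make_ud, random_ud
from oracles import overlap2d_bruteforce, vi_bruteforce


class TestExtractIsopleth:
    def test_uniform_ud_cell_count_and_area(self):
        ud = make_ud(np.ones((10, 10)), cell=50.0)
        region = extract_isopleth(ud, 0.95)
        assert len(region.cells) == 95
        assert region.area_ha == pytest.approx(23.75)  # 95 cells x 0.25 ha

    def test_core_area_nested_in_home_range(self, rng):
        ud = random_ud(rng)
        hr = extract_isopleth(ud, 0.95)
        ca = extract_isopleth(ud, 0.50)
        assert set(ca.cells) <= set(hr.cells)

    def test_point_mass_gives_single_cell(self):
        z = np.zeros((5, 5))
        z[2, 3] = 1.0
        ud = make_ud(z)
        for level in (0.5, 0.95):
            assert len(extract_isopleth(ud, level).cells) == 1

    def test_cumulative_mass_reaches_level_minimally(self, rng):
        ud = random_ud(rng)
        region = extract_isopleth(ud, 0.95)
        flat = ud.density.ravel()
        inside = flat[region.cells].sum()
        assert inside >= 0.95
        # dropping the least dense member cell must fall below the level
        assert inside - flat[region.cells].min() < 0.95

    def test_invalid_level(self, rng):
        with pytest.raises(ValueError):
            extract_isopleth(random_ud(rng), 1.0)


class TestOverlap2D:
    def test_identical_regions(self, rng):
        ud = random_ud(rng)
        r = extract_isopleth(ud, 0.95)
        assert overlap_2d(r, r) == (1.0, 1.0)

    def test_half_overlapping_strips(self):
        # A covers cells 0-9 of a uniform strip, B covers 5-14
        za = np.zeros((1, 15)); za[0, :10] = 1
        zb = np.zeros((1, 15)); zb[0, 5:] = 1
        ra = extract_isopleth(make_ud(za), 0.999)
        rb = extract_isopleth(make_ud(zb), 0.999)
        assert overlap_2d(ra, rb) == (0.5, 0.5)

    def test_disjoint_regions(self):
        za = np.zeros((2, 10)); za[0] = 1
        zb = np.zeros((2, 10)); zb[1] = 1
        ra = extract_isopleth(make_ud(za), 0.999)
        rb = extract_isopleth(make_ud(zb), 0.999)
        assert overlap_2d(ra, rb) == (0.0, 0.0)

    def test_different_grids_error(self):
        ra = extract_isopleth(make_ud(np.ones((5, 5))), 0.9)
        rb = extract_isopleth(make_ud(np.ones((6, 6))), 0.9)
        with pytest.raises(ValueError, match="different grids"):
            overlap_2d(ra, rb)


class TestVolumeOfIntersection:
    def test_identical_uds(self, rng):
        ud = random_ud(rng)
        assert volume_of_intersection(ud, ud) == pytest.approx(1.0)

    def test_three_cell_hand_example(self):
        ua = make_ud(np.array([[0.7, 0.3, 0.0]]))
        ub = make_ud(np.array([[0.0, 0.3, 0.7]]))
        assert volume_of_intersection(ua, ub) == pytest.approx(0.3)

    def test_disjoint_supports(self):
        ua = make_ud(np.array([[1.0, 0.0]]))
        ub = make_ud(np.array([[0.0, 1.0]]))
        assert volume_of_intersection(ua, ub) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            ua, ub = random_ud(rng), random_ud(rng, animal_id="b")
            vi = volume_of_intersection(ua, ub)
            assert vi == volume_of_intersection(ub, ua)
            assert 0.0 <= vi <= 1.0
            vic = volume_of_intersection(ua, ub, level=0.50)
            assert 0.0 <= vic <= 1.0

    def test_matches_bruteforce_on_random_grids(self, rng):
        for _ in range(25):
            ua, ub = random_ud(rng), random_ud(rng, animal_id="b")
            assert volume_of_intersection(ua, ub) == pytest.approx(
                vi_bruteforce(ua.density, ub.density), abs=1e-12
            )
            ra = extract_isopleth(ua, 0.95)
            rb = extract_isopleth(ub, 0.95)
            assert overlap_2d(ra, rb) == overlap2d_bruteforce(ra.cells, rb.cells)


class TestFindDyads:
    def test_identical_uds_form_one_dyad(self, rng):
        ud = random_ud(rng, animal_id="a")
        ud2 = random_ud(np.random.default_rng(12345), animal_id="b")
        regions = [extract_isopleth(u, 0.95) for u in (ud, ud2)]
        assert find_dyads(regions) == [Dyad("a", "b")]

    def test_disjoint_home_ranges_form_none(self):
        zs = [np.zeros((9, 9)) for _ in range(3)]
        for i, z in enumerate(zs):
            z[3 * i:3 * i + 3, :] = 1.0
        regions = [
            extract_isopleth(make_ud(z, animal_id=f"a{i}"), 0.6)
            for i, z in enumerate(zs)
        ]
        assert find_dyads(regions) == []

    def test_any_period_counts(self):
        # overlap only in the second period still qualifies the pair
        z1 = np.zeros((4, 4)); z1[0, :] = 1
        z2 = np.zeros((4, 4)); z2[3, :] = 1
        z_shift = np.zeros((4, 4)); z_shift[3, :2] = 1
        regions = [
            extract_isopleth(make_ud(z1, animal_id="a"), 0.9),
            extract_isopleth(make_ud(z_shift, animal_id="a"), 0.9),
            extract_isopleth(make_ud(z2, animal_id="b"), 0.9),
        ]
        assert find_dyads(regions) == [Dyad("a", "b")]


class TestIsoplethExport:
    def test_geojson_polygon_covers_region_area(self, rng):
        from shapely.geometry import shape

        region = ov.extract_isopleth(random_ud(rng), 0.95)
        feat = ov.isopleth_to_geojson(region)
        assert feat["properties"]["area_ha"] == pytest.approx(region.area_ha)
        geom = shape(feat["geometry"])
        assert geom.area == pytest.approx(region.area_ha * 1e4)


class TestAggregateBySow:
    @staticmethod
    def _rec(a, b, vi, pab=0.5, pba=0.25, period="P1", level=0.95):
        return OverlapRecord(Dyad(a, b), "week", period, level, pab, pba, vi)

    def test_mean_over_four_dyads(self):
        recs = [self._rec("s1", f"n{i}", vi) for i, vi in
                enumerate([0.1, 0.2, 0.3, 0.4])]
        out = aggregate_by_sow(recs)
        row = out[out.animal_id == "s1"].iloc[0]
        assert row.vi == pytest.approx(0.25)
        # ids are stored sorted, so s1 sits on the "b" side of every dyad and
        # her directional 2D value is the pba side of each record
        assert row.overlap_2d == pytest.approx(0.25)

    def test_single_dyad_passthrough(self):
        out = aggregate_by_sow([self._rec("s1", "s2", 0.42)])
        assert out[out.animal_id == "s1"].iloc[0].vi == pytest.approx(0.42)
        # the partner's directional 2D value is its own side of the record
        assert out[out.animal_id == "s2"].iloc[0].overlap_2d == pytest.approx(0.25)

    def test_order_invariance(self, rng):
        recs = [self._rec("s1", f"n{i}", float(v), period=f"P{i % 2}")
                for i, v in enumerate(rng.random(8))]
        a = aggregate_by_sow(recs)
        b = aggregate_by_sow(list(reversed(recs)))
        assert a.equals(b)
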