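import logging

import numpy as np
import pytest

from sounderspace import dbbmm
from sounderspace.dbbmm import (
    ErrorModel,
    bridge_variance,
    estimate_motion_variance,
    estimate_ud,
    make_grid,
    static_motion_variance,
)
from sounderspace.overlap import extract_isopleth

from conftest import brownian_track, make_traj


class TestBridgeVariance:
    def test_endpoint_is_pure_location_error(self):
        assert bridge_variance(0.0, 7200, 0.5, 20, 30) == pytest.approx(400.0)
        assert bridge_variance(1.0, 7200, 0.5, 20, 30) == pytest.approx(900.0)

    def test_midpoint_hand_arithmetic(self):
        # T a (1-a) sigma2 = 7200 * 0.25 * 0.5 = 900; error terms 2 * 0.25 * 400
        assert bridge_variance(0.5, 7200, 0.5, 20, 20) == pytest.approx(1100.0)

    def test_degenerate_bridge_is_zero(self):
        alphas = np.linspace(0, 1, 11)
        assert np.allclose(bridge_variance(alphas, 100.0, 0.0, 0.0, 0.0), 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(t_frac=-0.1, T=1.0, sigma2_m=1, delta_start=0, delta_end=0),
         dict(t_frac=0.5, T=-1.0, sigma2_m=1, delta_start=0, delta_end=0),
         dict(t_frac=0.5, T=1.0, sigma2_m=-1, delta_start=0, delta_end=0)],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            bridge_variance(**kwargs)


class TestMakeGrid:
    def test_origin_snapping_and_extent(self):
        tr = make_traj([0, 7200], [125.0, 125.0], [75.0, 75.0])
        g = make_grid([tr], cell=50.0, buffer=100.0)
        assert (g.x0, g.y0) == (0.0, -50.0)
        assert g.ncols >= 5 and g.nrows >= 5
        assert g.x0 % 50 == 0 and g.y0 % 50 == 0

    def test_override_returned_unchanged(self):
        tr = make_traj([0, 7200], [125.0, 125.0], [75.0, 75.0])
        g = make_grid([tr], cell=50.0, buffer=100.0)
        assert make_grid([tr], override=g) is g

    def test_override_must_cover_fixes(self):
        tr = make_traj([0, 7200], [125.0, 1e6], [75.0, 75.0])
        g = dbbmm.RasterGrid(0.0, 0.0, 50.0, 10, 10)
        with pytest.raises(ValueError, match="cover"):
            make_grid([tr], override=g)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            make_grid([])


class TestMotionVariance:
    def test_brownian_motion_recovered(self, rng):
        tr = brownian_track(rng, n=300, sigma2=0.4, delta=20.0)
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        assert np.median(prof.sigma2) == pytest.approx(0.4, rel=0.2)

    def test_variance_drop_detected(self, rng):
        # step variance halves at the midpoint: early sigma2 must exceed late
        n, dt = 400, 7200
        s1 = rng.normal(scale=np.sqrt(0.8 * dt), size=(n // 2, 2))
        s2 = rng.normal(scale=np.sqrt(0.2 * dt), size=(n // 2, 2))
        xy = np.cumsum(np.vstack([s1, s2]), axis=0)
        tr = make_traj(np.arange(n) * dt, xy[:, 0], xy[:, 1])
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        third = n // 3
        assert prof.sigma2[:third].mean() > prof.sigma2[-third:].mean()

    def test_stationary_fixes_give_zero_variance(self):
        n = 60
        tr = make_traj(np.arange(n) * 7200, np.full(n, 10.0), np.full(n, 20.0))
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        assert prof.sigma2.max() < 1e-6  # at the lower optimisation bound

    def test_short_track_static_fallback(self, rng, caplog):
        tr = brownian_track(rng, n=20)
        with caplog.at_level(logging.INFO, logger="sounderspace.dbbmm"):
            prof = estimate_motion_variance(tr, ErrorModel(20.0), window=29)
        assert len(np.unique(prof.sigma2)) == 1
        assert any("static" in r.message for r in caplog.records)

    def test_single_window_homogeneous_equals_static(self):
        # window spanning the whole track and the single-variance model
        # selected: the dynamic estimate collapses to the static MLE on the
        # same leave-one-out fixes
        tr = brownian_track(np.random.default_rng(0), n=29, sigma2=0.5)
        prof = estimate_motion_variance(tr, ErrorModel(20.0), window=29, margin=11)
        static = static_motion_variance(tr, ErrorModel(20.0))
        assert np.unique(prof.sigma2) == pytest.approx(static, rel=1e-6)

    def test_window_validation(self, rng):
        tr = brownian_track(rng, n=100)
        with pytest.raises(ValueError):
            estimate_motion_variance(tr, window=28)
        with pytest.raises(ValueError):
            estimate_motion_variance(tr, window=29, margin=15)


class TestEstimateUD:
    def test_unit_mass_and_nonnegative(self, rng):
        tr = brownian_track(rng, n=60)
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        ud = estimate_ud(tr, prof, make_grid([tr]), ErrorModel(20.0))
        assert ud.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ud.density >= 0).all()

    def test_two_fix_track_mass_near_segment(self):
        tr = make_traj([0, 7200], [0.0, 1000.0], [0.0, 0.0])
        prof = dbbmm.MotionVarianceProfile(np.zeros(2), 29, 11)
        grid = make_grid([tr], cell=50.0, buffer=500.0)
        ud = estimate_ud(tr, prof, grid, ErrorModel(20.0))
        # with sigma2=0 and delta=20 the kernel sd is <= 20 m: cells farther
        # than 100 m from the connecting segment hold essentially no mass
        yy = grid.ys[:, None] * np.ones(grid.ncols)[None, :]
        far = np.abs(yy) > 100.0  # segment lies on y = 0
        assert ud.density[far].sum() < 1e-6

    def test_integration_converges_in_n_int(self, rng):
        tr = brownian_track(rng, n=80, sigma2=0.3)
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        grid = make_grid([tr])
        u1 = estimate_ud(tr, prof, grid, ErrorModel(20.0), n_int=10)
        u2 = estimate_ud(tr, prof, grid, ErrorModel(20.0), n_int=20)
        assert np.abs(u1.density - u2.density).max() < 0.01

    def test_isopleth_area_monotone_in_error_and_variance(self, rng):
        tr = brownian_track(rng, n=100, sigma2=0.3)
        grid = make_grid([tr])
        prof = estimate_motion_variance(tr, ErrorModel(20.0))
        areas = []
        for delta in (10.0, 40.0, 80.0):
            ud = estimate_ud(tr, prof, grid, ErrorModel(delta))
            areas.append(extract_isopleth(ud, 0.95).area_ha)
        assert areas == sorted(areas)
        inflated = dbbmm.MotionVarianceProfile(prof.sigma2 * 4, 29, 11)
        ud_hi = estimate_ud(tr, inflated, grid, ErrorModel(20.0))
        ud_lo = estimate_ud(tr, prof, grid, ErrorModel(20.0))
        assert (extract_isopleth(ud_hi, 0.95).area_ha
                >= extract_isopleth(ud_lo, 0.95).area_ha)

    def test_all_gaps_too_long_errors(self):
        tr = make_traj([0, 100_000], [0.0, 10.0], [0.0, 0.0])
        prof = dbbmm.MotionVarianceProfile(np.zeros(2), 29, 11)
        with pytest.raises(ValueError, match="no usable bridges"):
            estimate_ud(tr, prof, make_grid([tr]), ErrorModel(20.0))
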