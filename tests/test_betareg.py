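import numpy as np
import pandas as pd
import pytest
from scipy import special

from sounderspace import betareg
from sounderspace.betareg import (
    aicc,
    aicc_rank,
    build_covariates,
    fit_beta_regression,
    odds_ratios,
    transform_boundary,
)


def simulate_beta_data(seed, n=500, beta=(0.0, 0.8, -0.5), phi=30.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    mu = special.expit(beta[0] + beta[1] * x1 + beta[2] * x2)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


class TestTransformBoundary:
    def test_zero_maps_to_half_over_n(self):
        assert transform_boundary(np.array([0.0]), 49)[0] == pytest.approx(
            0.5 / 49
        )

    def test_one_maps_inside(self):
        assert transform_boundary(np.array([1.0, 0.2]), 100)[0] == pytest.approx(0.995)

    def test_midpoint_fixed_and_noop_when_interior(self):
        y = np.array([0.5, 0.2, 0.8])
        assert np.array_equal(transform_boundary(y, 100), y)
        assert transform_boundary(np.array([0.5, 0.0]), 10)[0] == pytest.approx(
            0.5
        )


class TestFit:
    def test_intercept_only_symmetric_response(self):
        tbl = pd.DataFrame({"y": np.full(40, 0.5)})
        m = fit_beta_regression(tbl, "y", [])
        assert m.beta[0] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        tbl = simulate_beta_data(7)
        m = fit_beta_regression(tbl, "y", ["x1", "x2"])
        sx1 = tbl.x1.std(ddof=0)
        sx2 = tbl.x2.std(ddof=0)
        truth = {"x1": 0.8 * sx1, "x2": -0.5 * sx2}  # standardized scale
        for name, b, se in zip(m.coef_names[1:], m.beta[1:], m.se[1:]):
            assert abs(b - truth[name]) < 3 * se

    def test_fitted_loglik_beats_truth(self):
        tbl = simulate_beta_data(3)
        m = fit_beta_regression(tbl, "y", ["x1", "x2"])
        sx1, sx2 = tbl.x1.std(ddof=0), tbl.x2.std(ddof=0)
        true_model = betareg.BetaRegressionModel(
            terms=["x1", "x2"], response="y", coef_names=m.coef_names,
            beta=np.array([
                0.0 + 0.8 * tbl.x1.mean() - 0.5 * tbl.x2.mean(),
                0.8 * sx1, -0.5 * sx2,
            ]),
            phi=30.0, se=m.se, se_log_phi=0.0, loglik=0.0, k=4, n=len(tbl),
            converged=True, scalers=m.scalers,
        )
        assert m.loglik >= betareg.beta_loglik(true_model, tbl) - 1e-6

    def test_duplicated_covariate_raises_rank_error(self):
        tbl = simulate_beta_data(1)
        tbl["x3"] = tbl["x1"]
        with pytest.raises(ValueError, match="aliased"):
            fit_beta_regression(tbl, "y", ["x1", "x2", "x3"])

    def test_boundary_response_rejected(self):
        tbl = pd.DataFrame({"y": np.array([0.0, 0.5, 0.5] * 10)})
        with pytest.raises(ValueError, match="transform_boundary"):
            fit_beta_regression(tbl, "y", [])

    def test_standardization_invariance(self):
        tbl = simulate_beta_data(11)
        m1 = fit_beta_regression(tbl, "y", ["x1", "x2"])
        pre = tbl.copy()
        for c in ("x1", "x2"):
            pre[c] = (pre[c] - pre[c].mean()) / pre[c].std(ddof=0)
        m2 = fit_beta_regression(pre, "y", ["x1", "x2"])
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-6)

    def test_matches_independent_implementation(self):
        statsmodels = pytest.importorskip("statsmodels.othermod.betareg")
        tbl = simulate_beta_data(21, n=200)
        m = fit_beta_regression(tbl, "y", ["x1", "x2"])
        X = np.column_stack([
            np.ones(len(tbl)),
            (tbl.x1 - tbl.x1.mean()) / tbl.x1.std(ddof=0),
            (tbl.x2 - tbl.x2.mean()) / tbl.x2.std(ddof=0),
        ])
        ref = statsmodels.BetaModel(tbl.y.to_numpy(), X).fit(disp=0)
        assert np.allclose(ref.params[:3], m.beta, atol=1e-4)
        assert ref.llf == pytest.approx(m.loglik, abs=1e-5)


class TestAICc:
    def test_hand_arithmetic(self):
        # -2 loglik + 2k = 100 at k = 3, n = 20 -> 100 + 24/16 = 101.5
        assert aicc(loglik=-(100 - 6) / 2, k=3, n=20) == pytest.approx(101.5)

    def test_small_sample_guard(self):
        assert aicc(0.0, k=10, n=11) == np.inf

    def test_converges_to_aic_for_large_n(self):
        k, n = 5, 10**6
        assert abs(aicc(0.0, k, n) - 2 * k) < 1e-4 * k**2

    def test_identical_models_tie_and_are_plausible(self):
        tbl = simulate_beta_data(5)
        m1 = fit_beta_regression(tbl, "y", ["x1", "x2"])
        m2 = fit_beta_regression(tbl, "y", ["x1", "x2"])
        rank = aicc_rank([m1, m2])
        assert np.allclose(rank["delta_aicc"], 0.0)
        assert rank["plausible"].all()

    def test_mismatched_n_errors(self):
        m1 = fit_beta_regression(simulate_beta_data(5, n=100), "y", ["x1"])
        m2 = fit_beta_regression(simulate_beta_data(5, n=120), "y", ["x1"])
        with pytest.raises(ValueError, match="sample sizes"):
            aicc_rank([m1, m2])

    def test_true_model_usually_ranked_first(self):
        wins = 0
        reps = 20
        for s in range(reps):
            tbl = simulate_beta_data(100 + s)
            tbl["z1"] = np.random.default_rng(s).normal(size=len(tbl))
            models = [
                fit_beta_regression(tbl, "y", []),
                fit_beta_regression(tbl, "y", ["x1", "x2"]),
                fit_beta_regression(
                    tbl, "y",
                    ["x1", "x2", "z1", "x1:z1", "x2:z1", "x1:x2"],
                ),
            ]
            rank = aicc_rank(models)
            if rank["formula"].iloc[0] == "y ~ x1 + x2":
                wins += 1
        assert wins >= int(0.8 * reps)


class TestOddsRatios:
    def _model(self, beta, se):
        return betareg.BetaRegressionModel(
            terms=["x"], response="y", coef_names=["(Intercept)", "x"],
            beta=np.array([0.0, beta]), phi=10.0, se=np.array([0.1, se]),
            se_log_phi=0.1, loglik=0.0, k=3, n=50, converged=True,
        )

    def test_null_effect(self):
        out = odds_ratios(self._model(0.0, 0.1))
        row = out.iloc[0]
        assert row["or"] == pytest.approx(1.0)
        assert not row["excludes_one"]

    def test_hand_arithmetic_90pct(self):
        out = odds_ratios(self._model(0.5, 0.1))
        row = out.iloc[0]
        assert row["or"] == pytest.approx(1.6487, abs=1e-4)
        assert row["ci_lo"] == pytest.approx(1.399, abs=1e-3)
        assert row["ci_hi"] == pytest.approx(1.943, abs=1e-3)
        assert row["excludes_one"]

    def test_power_for_strong_effect(self):
        hits = 0
        reps = 25
        for s in range(reps):
            tbl = simulate_beta_data(500 + s, beta=(0.0, 0.8, -0.5))
            m = fit_beta_regression(tbl, "y", ["x1", "x2"])
            out = odds_ratios(m)
            if out[out.term == "x1"].iloc[0]["excludes_one"]:
                hits += 1
        assert hits >= int(0.85 * reps)


class TestBuildCovariates:
    def _region_and_polygons(self):
        from shapely.geometry import box
        from sounderspace.dbbmm import RasterGrid, UtilizationDistribution
        from sounderspace.overlap import extract_isopleth
        from sounderspace.tracks import AnimalAttributes, StudyPolygons

        z = np.zeros((5, 10))
        z[2, :] = 1.0  # a 10-cell strip at y in [100, 150)
        grid = RasterGrid(0.0, 0.0, 50.0, 10, 5)
        ud = UtilizationDistribution("s1", None, grid, z / z.sum())
        region = extract_isopleth(ud, 0.999)
        attrs = {"s1": AnimalAttributes("s1", 80.0, "adult", 6)}
        return region, attrs, StudyPolygons

    def test_partial_containment_percent(self):
        region, attrs, SP = self._region_and_polygons()
        from shapely.geometry import box

        # covers the first 3 cell centres of the strip
        polygons = SP(landfill=box(0, 100, 150, 150),
                      waste_cells=box(0, 100, 50, 150))
        out = build_covariates([region], polygons, attrs)
        assert out["%UD.LF"].iloc[0] == pytest.approx(30.0)
        assert out["Dist.WC"].iloc[0] == 0.0  # region touches the waste cells

    def test_full_containment_and_distance(self):
        region, attrs, SP = self._region_and_polygons()
        from shapely.geometry import box

        polygons = SP(landfill=box(-10, -10, 600, 300),
                      waste_cells=box(2000, 100, 2100, 150))
        out = build_covariates([region], polygons, attrs)
        assert out["%UD.LF"].iloc[0] == pytest.approx(100.0)
        # nearest boundary cell centre at x = 475 -> 1525 m to the polygon
        assert out["Dist.WC"].iloc[0] == pytest.approx(1.525)

    def test_missing_attribute_names_sow(self):
        region, _, SP = self._region_and_polygons()
        from shapely.geometry import box

        polygons = SP(landfill=box(0, 0, 100, 100),
                      waste_cells=box(0, 0, 50, 50))
        with pytest.raises(ValueError, match="s1"):
            build_covariates([region], polygons, {})
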