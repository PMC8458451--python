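"""Validation experiments for the pipeline's statistical machinery.

Each function runs a self-contained simulation experiment against a known
ground truth or closed form and returns plain numbers: motion-variance
recovery on Brownian tracks, home-range area of a stationary OU track versus
the bivariate-normal closed form, beta-regression coefficient recovery and
Wald-interval coverage, and the paired-seed scenario contrasts (territorial
vs shared space use; attraction vs avoidance at the attractor).  The
experiments are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from shapely.geometry import Point

from . import betareg, dbbmm, interaction, overlap, synthetic, tracks
from .synthetic import CHI2_95_2

import pandas as pd


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence((int(seed), int(salt))).generate_state(1)[0]
               % (2**31 - 1))


# ---------------------------------------------------------------------------
# Closed-form and recovery experiments
# ---------------------------------------------------------------------------

def brownian_sigma_recovery(
    seed: int, n_reps: int = 10, n_fix: int = 300,
    sigma2: float = 0.4, delta: float = 20.0, dt: float = 7200.0,
) -> dict:
    """Median relative error of dBBMM motion variance on pure Brownian tracks."""
    medians = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, 100 + rep))
        steps = rng.normal(scale=np.sqrt(sigma2 * dt), size=(n_fix, 2))
        xy = np.cumsum(steps, axis=0) + rng.normal(scale=delta, size=(n_fix, 2))
        tr = tracks.Trajectory("bm", 2016, np.arange(n_fix) * int(dt),
                               xy[:, 0], xy[:, 1])
        prof = dbbmm.estimate_motion_variance(tr, dbbmm.ErrorModel(delta))
        medians.append(float(np.median(prof.sigma2)))
    med = float(np.median(medians))
    return {
        "sigma2_true": sigma2,
        "sigma2_est_median": med,
        "rel_error": abs(med - sigma2) / sigma2,
        "n_reps": n_reps,
    }


def stationary_ou_area_ratio(
    seed: int, n_tracks: int = 5, s: float = 326.0,
    duration_days: int = 167, delta: float = 20.0,
) -> dict:
    """dBBMM 95% home-range area of stationary OU tracks vs the closed form.

    The stationary distribution is isotropic bivariate normal with per-axis
    SD ``s``, so the analytic 95% home range is ``pi * chi2_{0.95,2} * s^2``.
    Returns the median area ratio over replicate tracks.
    """
    analytic_ha = np.pi * CHI2_95_2 * s**2 / 1e4
    ratios = []
    err = dbbmm.ErrorModel(delta)
    for rep in range(n_tracks):
        cfg = synthetic.SimulationConfig(
            centers=((0.0, 0.0),), seed=_child_seed(seed, 200 + rep),
            duration_days=duration_days, s_m=s, delta_gps=delta,
        )
        (tr,), _ = synthetic.simulate_tracks(cfg)
        prof = dbbmm.estimate_motion_variance(tr, err)
        grid = dbbmm.make_grid([tr])
        ud = dbbmm.estimate_ud(tr, prof, grid, err)
        hr = overlap.extract_isopleth(ud, 0.95)
        ratios.append(hr.area_ha / analytic_ha)
    return {
        "analytic_area_ha": analytic_ha,
        "median_ratio": float(np.median(ratios)),
        "n_tracks": n_tracks,
    }


def beta_regression_calibration(
    seed: int, n_sims: int = 200, n: int = 500,
    beta=(0.0, 0.8, -0.5), phi: float = 30.0,
) -> dict:
    """Coefficient recovery and 90% Wald-interval coverage for beta regression."""
    z90 = betareg.Z90
    covered = 0
    checked = 0
    max_abs_z = 0.0
    for s in range(n_sims):
        rng = np.random.default_rng(_child_seed(seed, 300 + s))
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        mu = special.expit(beta[0] + beta[1] * x1 + beta[2] * x2)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        tbl = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        m = betareg.fit_beta_regression(tbl, "y", ["x1", "x2"])
        if not m.converged:
            continue
        truth = [beta[1] * x1.std(), beta[2] * x2.std()]  # standardized scale
        for j, bt in enumerate(truth):
            est, se = m.beta[j + 1], m.se[j + 1]
            max_abs_z = max(max_abs_z, abs(est - bt) / se)
            covered += (est - z90 * se) <= bt <= (est + z90 * se)
            checked += 1
    return {
        "coverage_pct": 100.0 * covered / checked,
        "max_abs_z": max_abs_z,
        "n_sims": n_sims,
        "n_intervals": checked,
    }


# ---------------------------------------------------------------------------
# Scenario contrasts
# ---------------------------------------------------------------------------

def _season_dyad_metrics(kind: str, seed: int, duration_days: int = 107):
    """Season-long home-range 2D overlap and VI for a two-animal scenario."""
    trajs, _, _ = synthetic.simulate_dyad_scenario(
        kind, seed, duration_days=duration_days
    )
    err = dbbmm.ErrorModel(20.0)
    grid = dbbmm.make_grid(trajs)
    uds = []
    for tr in trajs:
        prof = dbbmm.estimate_motion_variance(tr, err)
        uds.append(dbbmm.estimate_ud(tr, prof, grid, err))
    regions = [overlap.extract_isopleth(u, 0.95) for u in uds]
    pab, pba = overlap.overlap_2d(regions[0], regions[1])
    vi = overlap.volume_of_intersection(uds[0], uds[1], level=0.95)
    return 0.5 * (pab + pba), vi


def territorial_vs_shared_vi(
    seed: int, n_pairs: int = 20, duration_days: int = 107
) -> dict:
    """Paired-seed contrast: territorial centres vs a shared centre.

    Counts pairs in which the territorial scenario's home-range VI is
    strictly below the shared-centre scenario's, and returns the scenario
    means including the 2D-overlap / VI territoriality signature.
    """
    wins = 0
    terr_2d, terr_vi, shared_vi = [], [], []
    for p in range(n_pairs):
        s = _child_seed(seed, 400 + p)
        o2_t, vi_t = _season_dyad_metrics("territorial", s, duration_days)
        _, vi_s = _season_dyad_metrics("shared", s, duration_days)
        wins += vi_t < vi_s
        terr_2d.append(o2_t)
        terr_vi.append(vi_t)
        shared_vi.append(vi_s)
    return {
        "wins": wins,
        "n_pairs": n_pairs,
        "territorial_mean_2d": float(np.mean(terr_2d)),
        "territorial_mean_vi": float(np.mean(terr_vi)),
        "shared_mean_vi": float(np.mean(shared_vi)),
    }


def attraction_vs_avoidance_hai(
    seed: int, n_pairs: int = 20, duration_days: int = 40,
    p_visit: float = 0.5,
) -> dict:
    """Paired-seed contrast of HAI at the attractor polygon.

    Both scenarios share geometry and seeds and differ only in the coupling
    of the two animals' nightly attractor excursions.
    """
    s_m = synthetic.DEFAULT_S
    att = synthetic.AttractorSpec(
        x=0.5 * synthetic.TERRITORIAL_SEPARATION_FACTOR * s_m, y=0.0,
        p_visit=p_visit,
    )
    landfill = Point(att.x, att.y).buffer(400.0, quad_segs=32)
    thr = interaction.InteractionThresholds()
    wins = 0
    hai_att, hai_avo = [], []
    for p in range(n_pairs):
        s = _child_seed(seed, 500 + p)
        vals = {}
        for coupling in ("attraction", "avoidance"):
            trajs, _, _ = synthetic.simulate_dyad_scenario(
                "territorial", s, duration_days=duration_days,
                attractor=att, coupling=coupling,
            )
            h = interaction.half_weight_association(
                trajs[0], trajs[1], landfill, thr
            )
            vals[coupling] = 0.0 if h is None else h
        wins += vals["attraction"] > vals["avoidance"]
        hai_att.append(vals["attraction"])
        hai_avo.append(vals["avoidance"])
    return {
        "wins": wins,
        "n_pairs": n_pairs,
        "attraction_mean_hai": float(np.mean(hai_att)),
        "avoidance_mean_hai": float(np.mean(hai_avo)),
    }


def independence_null_prox(
    seed: int, n_seeds: int = 50, duration_days: int = 30
) -> dict:
    """Mean Prox for two independent OU tracks with far-apart centres."""
    s_m = synthetic.DEFAULT_S
    thr = interaction.InteractionThresholds()
    proxs = []
    for k in range(n_seeds):
        cfg = synthetic.SimulationConfig(
            centers=((0.0, 0.0), (10.0 * s_m, 0.0)),
            seed=_child_seed(seed, 600 + k), duration_days=duration_days,
        )
        trajs, _ = synthetic.simulate_tracks(cfg)
        p, _, _ = interaction.proximity_index(trajs[0], trajs[1], thr)
        proxs.append(0.0 if p is None else p)
    return {"mean_prox": float(np.mean(proxs)), "n_seeds": n_seeds}
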