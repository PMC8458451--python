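"""Config-driven orchestration: simulate -> UDs -> overlap -> interactions -> models.

Each stage is a plain function over in-memory objects so the analysis
scripts, tests and CLI can drive them independently; :func:`run_pipeline`
chains them from one declarative (YAML-compatible) configuration and writes
tidy CSV artifacts plus a machine-readable run manifest.  Identical
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, betareg, dbbmm, interaction, overlap, synthetic, tracks

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "output_dir": "runs/demo",
    "simulate": {
        "cohorts": [2014, 2016],
        "duration_days": None,       # None -> the full cohort tracking range
        "attractor_visit_prob": 0.3,
    },
    "scales": ["season", "month", "week"],
    "dbbmm": {"window": 29, "margin": 11, "delta": 20.0, "cell": 50.0,
              "buffer": 1000.0, "n_int": 10, "max_gap_h": 8.0},
    "thresholds": {"dc": 50.0, "tc": 600.0, "vi_gate": 0.1},
    "min_fixes": 24,
    "models": {"responses": ["vi", "overlap_2d"]},
}


def merge_config(user: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: Mapping[str, Any]) -> None:
    for scale in cfg["scales"]:
        if scale not in tracks.SCALES:
            raise ValueError(f"config: unknown scale {scale!r}")
    d = cfg["dbbmm"]
    if d["window"] % 2 == 0 or d["window"] < 2 * d["margin"] + 1:
        raise ValueError("config: dbbmm window/margin invalid")
    for key in ("delta", "cell", "buffer"):
        if d[key] < 0 or (key == "cell" and d[key] <= 0):
            raise ValueError(f"config: dbbmm {key} invalid")
    t = cfg["thresholds"]
    if t["dc"] <= 0 or t["tc"] <= 0 or not 0 <= t["vi_gate"] <= 1:
        raise ValueError("config: thresholds invalid")


def config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: Mapping[str, Any]):
    """Simulate the configured cohorts; returns (trajectories, polygons,
    attributes, weather, truths-by-cohort)."""
    sim = cfg["simulate"]
    all_trajs: list[tracks.Trajectory] = []
    attributes: dict[str, tracks.AnimalAttributes] = {}
    weather_frames = []
    polygons = None
    truths = {}
    for cohort in sim["cohorts"]:
        sc = synthetic.default_cohort_config(
            int(cohort),
            seed=int(cfg["seed"]) * 1000 + int(cohort) % 100,
            duration_days=sim.get("duration_days"),
            attractor_visit_prob=sim.get("attractor_visit_prob", 0.3),
        )
        trajs, truth = synthetic.simulate_tracks(sc)
        poly, attrs, weather = synthetic.generate_covariates(truth, sc)
        all_trajs.extend(trajs)
        attributes.update(attrs)
        weather_frames.append(weather)
        truths[int(cohort)] = truth
        if polygons is None:
            polygons = poly
    weather = (
        pd.concat(weather_frames, ignore_index=True)
        .drop_duplicates(subset="date")
        .sort_values("date")
        .reset_index(drop=True)
    )
    return all_trajs, polygons, attributes, weather, truths


def stage_uds(
    trajs: list[tracks.Trajectory], cfg: Mapping[str, Any]
) -> tuple[dict, dict]:
    """Estimate per-animal, per-period UDs on one shared grid per cohort.

    Returns (uds, period_trajs): both keyed (animal_id, scale, period_label).
    """
    d = cfg["dbbmm"]
    err = dbbmm.ErrorModel(delta=float(d["delta"]))
    by_cohort: dict[int, list[tracks.Trajectory]] = {}
    for tr in trajs:
        by_cohort.setdefault(tr.cohort_year, []).append(tr)
    uds: dict[tuple[str, str, str], dbbmm.UtilizationDistribution] = {}
    period_trajs: dict[tuple[str, str, str], tracks.Trajectory] = {}
    for cohort, cohort_trajs in sorted(by_cohort.items()):
        grid = dbbmm.make_grid(cohort_trajs, cell=float(d["cell"]),
                               buffer=float(d["buffer"]))
        for tr in cohort_trajs:
            profile_full = dbbmm.estimate_motion_variance(
                tr, err, window=int(d["window"]), margin=int(d["margin"])
            )
            for scale in cfg["scales"]:
                for period, sub in tracks.partition_periods(
                    tr, scale, min_fixes=int(cfg["min_fixes"])
                ):
                    idx = np.searchsorted(tr.times, sub.times)
                    profile = dbbmm.MotionVarianceProfile(
                        profile_full.sigma2[idx],
                        window=profile_full.window, margin=profile_full.margin,
                    )
                    try:
                        ud = dbbmm.estimate_ud(
                            sub, profile, grid, err,
                            n_int=int(d["n_int"]),
                            max_gap=float(d["max_gap_h"]) * 3600.0,
                            period=period,
                        )
                    except ValueError as exc:
                        log.warning("UD failed for %s %s %s: %s",
                                    tr.animal_id, scale, period.label, exc)
                        continue
                    key = (tr.animal_id, scale, period.label)
                    uds[key] = ud
                    period_trajs[key] = sub
    return uds, period_trajs


def ud_area_summary(uds: Mapping, cohort_of: Mapping[str, int]) -> pd.DataFrame:
    """Mean +/- SD of home-range and core-area sizes per scale and cohort."""
    rows = []
    for (animal, scale, period), ud in uds.items():
        for level, name in ((0.95, "HR"), (0.50, "CA")):
            region = overlap.extract_isopleth(ud, level)
            rows.append(
                {
                    "cohort": cohort_of.get(animal, 0), "scale": scale,
                    "period": period, "animal_id": animal, "ud_level": name,
                    "area_ha": region.area_ha,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["cohort", "scale", "ud_level"], as_index=False)["area_ha"]
        .agg(mean="mean", sd="std", n="count")
    )


def stage_overlap(uds: Mapping, cfg: Mapping[str, Any]):
    """Isopleths, cohort dyads, overlap records and per-sow aggregates."""
    animal_cohort: dict[str, int] = {}
    for (animal, scale, period), ud in uds.items():
        year = 2014 if animal.startswith("S14") else 2016
        animal_cohort[animal] = year
    records: list[overlap.OverlapRecord] = []
    dyads_by_cohort: dict[int, list[overlap.Dyad]] = {}
    for year in sorted(set(animal_cohort.values())):
        cohort_uds = {
            key: ud for key, ud in uds.items() if animal_cohort[key[0]] == year
        }
        hr_regions = [
            overlap.extract_isopleth(ud, overlap.HOME_RANGE_LEVEL)
            for ud in cohort_uds.values()
        ]
        dyads = overlap.find_dyads(hr_regions)
        dyads_by_cohort[year] = dyads
        records.extend(overlap.compute_overlap_records(cohort_uds, dyads))
    aggregates = overlap.aggregate_by_sow(records)
    return records, aggregates, dyads_by_cohort, animal_cohort


def stage_interactions(
    dyads_by_cohort: Mapping[int, list],
    records,
    period_trajs: Mapping,
    polygons: tracks.StudyPolygons,
    cfg: Mapping[str, Any],
):
    t = cfg["thresholds"]
    thr = interaction.InteractionThresholds(
        dc=float(t["dc"]), tc=float(t["tc"]), vi_gate=float(t["vi_gate"])
    )
    all_dyads = [d for dyads in dyads_by_cohort.values() for d in dyads]
    return interaction.compute_interactions(
        all_dyads, records, period_trajs, polygons, thr
    )


def stage_models(
    uds: Mapping,
    aggregates: pd.DataFrame,
    polygons: tracks.StudyPolygons,
    attributes: Mapping[str, tracks.AnimalAttributes],
    weather: pd.DataFrame,
    animal_cohort: Mapping[str, int],
    cfg: Mapping[str, Any],
):
    """Beta-regression model selection per scale and response.

    Returns (selection tables, odds-ratio tables, covariate table); scales
    whose merged table is too small to fit are skipped with a log entry.
    """
    regions = []
    for ud in uds.values():
        for level in (overlap.HOME_RANGE_LEVEL, overlap.CORE_AREA_LEVEL):
            regions.append(overlap.extract_isopleth(ud, level))
    cov = betareg.build_covariates(
        regions, polygons, attributes, weather,
        cohort_of={a: (0 if y == min(animal_cohort.values()) else 1)
                   for a, y in animal_cohort.items()},
    )
    merged = cov.merge(
        aggregates, on=["animal_id", "scale", "period", "ud_level"], how="inner"
    )
    selections: dict[tuple[str, str], pd.DataFrame] = {}
    ors: dict[tuple[str, str], pd.DataFrame] = {}
    for scale in cfg["scales"]:
        sub = merged[merged["scale"] == scale].reset_index(drop=True)
        for response in cfg["models"]["responses"]:
            if len(sub) < 12:
                log.info("skipping %s/%s models: only %d rows", scale,
                         response, len(sub))
                continue
            tbl = sub.copy()
            tbl[response] = betareg.transform_boundary(
                tbl[response].to_numpy(), len(tbl)
            )
            models = []
            for terms in betareg.default_candidate_models(scale):
                if len(tbl) <= len(terms) + 3:
                    continue
                try:
                    models.append(
                        betareg.fit_beta_regression(tbl, response, terms)
                    )
                except ValueError as exc:
                    log.warning("model %s failed on %s/%s: %s",
                                terms, scale, response, exc)
            if not models:
                continue
            rank = betareg.aicc_rank(models)
            selections[(scale, response)] = rank
            if len(rank):
                top = next(
                    m for m in models
                    if m.converged and m.formula == rank["formula"].iloc[0]
                )
                ors[(scale, response)] = betareg.odds_ratios(top)
    return selections, ors, merged


def save_uds(path, uds: Mapping) -> None:
    """Cache UDs to a compressed npz keyed ``animal|scale|period``."""
    arrays = {}
    meta = {}
    for (animal, scale, period), ud in uds.items():
        key = f"{animal}|{scale}|{period}"
        arrays[key] = ud.density.astype(np.float32)
        g = ud.grid
        meta[key] = {
            "grid": [g.x0, g.y0, g.cell, g.ncols, g.nrows],
            "period": None if ud.period is None else {
                "scale": ud.period.scale, "label": ud.period.label,
                "start": ud.period.start.isoformat(),
                "end": ud.period.end.isoformat(),
            },
        }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_uds(path) -> dict:
    from datetime import datetime

    from .dbbmm import RasterGrid, UtilizationDistribution
    from .tracks import PeriodSpec

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        out = {}
        for key, m in meta.items():
            animal, scale, period = key.split("|")
            x0, y0, cell, ncols, nrows = m["grid"]
            grid = RasterGrid(x0, y0, cell, int(ncols), int(nrows))
            p = None
            if m["period"] is not None:
                p = PeriodSpec(
                    m["period"]["scale"], m["period"]["label"],
                    datetime.fromisoformat(m["period"]["start"]),
                    datetime.fromisoformat(m["period"]["end"]),
                )
            dens = data[key].astype(float)
            dens /= dens.sum()  # float32 round-trip renormalization
            out[(animal, scale, period)] = UtilizationDistribution(
                animal_id=animal, period=p, grid=grid, density=dens
            )
    return out


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(user_config: Mapping[str, Any] | None = None) -> Path:
    """Run every stage and write artifacts; returns the run directory.

    On stage failure the manifest names the failed stage and partial
    artifacts are retained; the exception propagates.
    """
    cfg = merge_config(user_config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "stages_completed": [],
        "failed_stage": None,
    }

    def _checkpoint():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "simulate"
    try:
        trajs, polygons, attributes, weather, _ = stage_simulate(cfg)
        tracks.write_tracks(trajs, outdir / "telemetry.csv")
        synthetic.write_polygons(polygons, outdir / "polygons.geojson")
        synthetic.write_attributes(attributes, outdir / "attributes.csv")
        weather.to_csv(outdir / "weather.csv", index=False)
        manifest["stages_completed"].append(stage)
        _checkpoint()

        stage = "ud"
        uds, period_trajs = stage_uds(trajs, cfg)
        cohort_of = {tr.animal_id: tr.cohort_year for tr in trajs}
        ud_area_summary(uds, cohort_of).to_csv(
            outdir / "ud_area_summary.csv", index=False
        )
        manifest["stages_completed"].append(stage)
        _checkpoint()

        stage = "overlap"
        records, aggregates, dyads_by_cohort, animal_cohort = stage_overlap(
            uds, cfg
        )
        overlap.overlap_records_frame(records).to_csv(
            outdir / "overlap_records.csv", index=False
        )
        aggregates.to_csv(outdir / "sow_overlap_aggregates.csv", index=False)
        pd.DataFrame(
            {
                "cohort": [y for y, ds in sorted(dyads_by_cohort.items())
                           for _ in ds],
                "animal_a": [d.animal_a for _, ds in sorted(dyads_by_cohort.items())
                             for d in ds],
                "animal_b": [d.animal_b for _, ds in sorted(dyads_by_cohort.items())
                             for d in ds],
            }
        ).to_csv(outdir / "dyads.csv", index=False)
        manifest["stages_completed"].append(stage)
        _checkpoint()

        stage = "interact"
        irecords = stage_interactions(
            dyads_by_cohort, records, period_trajs, polygons, cfg
        )
        interaction.interaction_records_frame(irecords).to_csv(
            outdir / "interaction_records.csv", index=False
        )
        interaction.summarize_interactions(irecords, cohort_of).to_csv(
            outdir / "interaction_summary.csv", index=False
        )
        manifest["stages_completed"].append(stage)
        _checkpoint()

        stage = "model"
        selections, ors, merged = stage_models(
            uds, aggregates, polygons, attributes, weather, animal_cohort, cfg
        )
        merged.to_csv(outdir / "model_table.csv", index=False)
        sel_frames = []
        for (scale, response), df in sorted(selections.items()):
            df = df.copy()
            df.insert(0, "scale", scale)
            df.insert(1, "response", response)
            sel_frames.append(df)
        (pd.concat(sel_frames, ignore_index=True) if sel_frames
         else pd.DataFrame()).to_csv(outdir / "model_selection.csv", index=False)
        or_frames = []
        for (scale, response), df in sorted(ors.items()):
            df = df.copy()
            df.insert(0, "scale", scale)
            df.insert(1, "response", response)
            or_frames.append(df)
        (pd.concat(or_frames, ignore_index=True) if or_frames
         else pd.DataFrame()).to_csv(outdir / "odds_ratios.csv", index=False)
        manifest["stages_completed"].append(stage)
        _checkpoint()
    except Exception:
        manifest["failed_stage"] = stage
        _checkpoint()
        raise
    return outdir
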