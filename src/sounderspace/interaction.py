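"""Dyadic dynamic-interaction indices: proximity ratio and half-weight association.

Two fixes of a dyad are simultaneous in space and time when they are < 50 m
and < 10 min apart (strict inequalities).  The proximity index (Prox) is the
ratio of space-and-time-simultaneous pairs to time-simultaneous pairs; the
half-weight association index (HAI) compares joint occurrences inside a
shared-area polygon (landfill boundary, waste cells) against solitary
occurrences there.  Indices are computed only for dyads whose home-range VI
exceeds a gate (default 0.1) in the period, and undefined values propagate
as missing, never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .overlap import Dyad, OverlapRecord
from .tracks import StudyPolygons, Trajectory, match_simultaneous

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionThresholds:
    dc: float = 50.0        # distance threshold, metres
    tc: float = 600.0       # time threshold, seconds
    vi_gate: float = 0.1    # minimum home-range VI for index calculation

    def __post_init__(self) -> None:
        if self.dc <= 0 or self.tc <= 0:
            raise ValueError("dc and tc must be positive")
        if not 0.0 <= self.vi_gate < 1.0:
            raise ValueError("vi_gate must lie in [0, 1)")


@dataclass
class InteractionRecord:
    dyad: Dyad
    scale: str
    period_label: str
    n_time_simultaneous: int
    n_space_time_simultaneous: int
    prox: float | None
    hai_landfill: float | None
    hai_wastecell: float | None


def _covers(poly: BaseGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boundary-inclusive point-in-polygon for coordinate arrays."""
    if len(x) == 0:
        return np.zeros(0, dtype=bool)
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    return shapely.covers(poly, pts)


def proximity_index(
    a: Trajectory, b: Trajectory, thr: InteractionThresholds | None = None
) -> tuple[float | None, int, int]:
    """(Prox, n_time_simultaneous, n_space_time_simultaneous).

    Prox is None (undefined) when no temporally simultaneous pairs exist.
    """
    thr = thr or InteractionThresholds()
    pairs = match_simultaneous(a, b, time_tol=thr.tc)
    n_time = len(pairs)
    if n_time == 0:
        return None, 0, 0
    ai, bi = pairs[:, 0], pairs[:, 1]
    d = np.hypot(a.x[ai] - b.x[bi], a.y[ai] - b.y[bi])
    n_st = int((d < thr.dc).sum())
    return n_st / n_time, n_time, n_st


def half_weight_association(
    a: Trajectory,
    b: Trajectory,
    shared: BaseGeometry,
    thr: InteractionThresholds | None = None,
) -> float | None:
    """HAI = n_joint / (n_joint + 0.5 * (n_a_solo + n_b_solo)) over ``shared``.

    A joint event is a temporally simultaneous pair with both fixes inside
    the polygon and < dc apart; a joint event consumes both fixes, so a fix
    cannot also be counted solitary.  Solitary counts include every other fix
    of the period lying inside the polygon.  Undefined (None) when no fix of
    either animal ever enters the polygon.
    """
    thr = thr or InteractionThresholds()
    if shared is None or shared.is_empty or not shared.is_valid:
        raise ValueError("shared polygon missing or invalid")
    in_a = _covers(shared, a.x, a.y)
    in_b = _covers(shared, b.x, b.y)
    pairs = match_simultaneous(a, b, time_tol=thr.tc)
    joint_a = np.zeros(len(a), dtype=bool)
    joint_b = np.zeros(len(b), dtype=bool)
    if len(pairs):
        ai, bi = pairs[:, 0], pairs[:, 1]
        d = np.hypot(a.x[ai] - b.x[bi], a.y[ai] - b.y[bi])
        joint = (d < thr.dc) & in_a[ai] & in_b[bi]
        joint_a[ai[joint]] = True
        joint_b[bi[joint]] = True
    n_joint = int(joint_a.sum())
    n_a_solo = int((in_a & ~joint_a).sum())
    n_b_solo = int((in_b & ~joint_b).sum())
    if n_joint + n_a_solo + n_b_solo == 0:
        return None
    return n_joint / (n_joint + 0.5 * (n_a_solo + n_b_solo))


def compute_interactions(
    dyads: Sequence[Dyad],
    overlap_records: Sequence[OverlapRecord],
    trajs: Mapping[tuple[str, str, str], Trajectory],
    polygons: StudyPolygons,
    thr: InteractionThresholds | None = None,
    *,
    home_range_level: float = 0.95,
) -> list[InteractionRecord]:
    """Interaction indices for every gated dyad x (scale, period).

    ``trajs`` maps (animal_id, scale, period_label) to the period-clipped
    trajectory.  A dyad-period is evaluated only when its home-range VI
    exceeds ``thr.vi_gate``; dyad-periods lacking an overlap record are
    skipped with a warning.
    """
    thr = thr or InteractionThresholds()
    vi_by_key: dict[tuple[str, str, str, str], float] = {}
    periods: set[tuple[str, str]] = set()
    for r in overlap_records:
        if r.ud_level == home_range_level:
            vi_by_key[(r.dyad.animal_a, r.dyad.animal_b, r.scale, r.period_label)] = r.vi
            periods.add((r.scale, r.period_label))
    records: list[InteractionRecord] = []
    for scale, period in sorted(periods):
        for dyad in dyads:
            a_id, b_id = dyad.animal_a, dyad.animal_b
            key = (a_id, b_id, scale, period)
            ta = trajs.get((a_id, scale, period))
            tb = trajs.get((b_id, scale, period))
            if ta is None or tb is None:
                continue
            if key not in vi_by_key:
                log.warning("no VI for dyad %s-%s in %s %s; skipped",
                            a_id, b_id, scale, period)
                continue
            if not vi_by_key[key] > thr.vi_gate:
                log.info("dyad %s-%s %s %s below VI gate (%.3f <= %.2f)",
                         a_id, b_id, scale, period, vi_by_key[key], thr.vi_gate)
                continue
            prox, n_time, n_st = proximity_index(ta, tb, thr)
            hai_lf = half_weight_association(ta, tb, polygons.landfill, thr)
            hai_wc = half_weight_association(ta, tb, polygons.waste_cells, thr)
            records.append(
                InteractionRecord(
                    dyad=dyad, scale=scale, period_label=period,
                    n_time_simultaneous=n_time, n_space_time_simultaneous=n_st,
                    prox=prox, hai_landfill=hai_lf, hai_wastecell=hai_wc,
                )
            )
    return records


def interaction_records_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_a": [r.dyad.animal_a for r in records],
            "animal_b": [r.dyad.animal_b for r in records],
            "scale": [r.scale for r in records],
            "period": [r.period_label for r in records],
            "n_time_simultaneous": [r.n_time_simultaneous for r in records],
            "n_space_time_simultaneous": [
                r.n_space_time_simultaneous for r in records
            ],
            "prox": [math.nan if r.prox is None else r.prox for r in records],
            "hai_landfill": [
                math.nan if r.hai_landfill is None else r.hai_landfill
                for r in records
            ],
            "hai_wastecell": [
                math.nan if r.hai_wastecell is None else r.hai_wastecell
                for r in records
            ],
        }
    )


def summarize_interactions(
    records: Sequence[InteractionRecord],
    cohort_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-scale (and optionally per-cohort) mean +/- SD of Prox and HAI.

    Mirrors the shape of the study's interaction-summary table: one row per
    cohort x index x scale with mean and SD over dyad-periods; missing index
    values are excluded from the moments rather than treated as zero.
    """
    df = interaction_records_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["cohort", "index", "scale", "mean", "sd", "n"])
    if cohort_of is not None:
        df["cohort"] = [cohort_of.get(a, -1) for a in df["animal_a"]]
    else:
        df["cohort"] = 0
    long = df.melt(
        id_vars=["cohort", "scale"],
        value_vars=["prox", "hai_landfill", "hai_wastecell"],
        var_name="index", value_name="value",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["cohort", "index", "scale"], as_index=False)["value"]
        .agg(mean="mean", sd="std", n="count")
    )
    return out
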