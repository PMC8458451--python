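"""Telemetry data model, I/O and temporal partitioning.

Trajectories are time-ordered projected GPS fixes for one animal, held as
numpy arrays (POSIX seconds, metres).  Periods partition a cohort's tracking
range into season / month / week windows; dyadic analyses additionally need
temporal alignment of two trajectories, provided by :func:`match_simultaneous`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta, timezone
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

SCALES = ("season", "month", "week")


class Fix(NamedTuple):
    """A single GPS fix: UTC instant (POSIX seconds) and projected metres."""

    timestamp: int
    x: float
    y: float


@dataclass
class Trajectory:
    """Time-ordered fixes for one animal.

    ``times`` are int64 POSIX seconds (UTC), strictly increasing; ``x``/``y``
    are projected coordinates in metres.  At least two fixes are required.
    """

    animal_id: str
    cohort_year: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) < 2:
            raise ValueError(
                f"trajectory {self.animal_id!r} needs >= 2 fixes, got {len(self.times)}"
            )
        if not (np.diff(self.times) > 0).all():
            raise ValueError(f"timestamps of {self.animal_id!r} not strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"non-finite coordinates in trajectory {self.animal_id!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def fixes(self) -> Iterator[Fix]:
        for t, x, y in zip(self.times, self.x, self.y):
            yield Fix(int(t), float(x), float(y))

    def slice_window(self, start_s: int, end_s: int) -> "Trajectory | None":
        """Sub-trajectory with times in [start_s, end_s); None if < 2 fixes."""
        m = (self.times >= start_s) & (self.times < end_s)
        if m.sum() < 2:
            return None
        return replace(self, times=self.times[m], x=self.x[m], y=self.y[m])


@dataclass(frozen=True)
class PeriodSpec:
    """A temporal analysis window: [start, end), UTC."""

    scale: str
    label: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.start < self.end:
            raise ValueError(f"period {self.label}: start must precede end")

    @property
    def start_s(self) -> int:
        return int(self.start.timestamp())

    @property
    def end_s(self) -> int:
        return int(self.end.timestamp())


@dataclass(frozen=True)
class StudyPolygons:
    """Landfill boundary, waste cells and (optional) habitat cover polygons."""

    landfill: BaseGeometry
    waste_cells: BaseGeometry
    habitat_blhw: BaseGeometry | None = None

    def __post_init__(self) -> None:
        for name in ("landfill", "waste_cells"):
            geom = getattr(self, name)
            if geom is None or geom.is_empty or not geom.is_valid:
                raise ValueError(f"{name} polygon missing or invalid")
        if self.habitat_blhw is not None and not self.habitat_blhw.is_valid:
            raise ValueError("habitat polygon invalid")


@dataclass(frozen=True)
class AnimalAttributes:
    animal_id: str
    mass_kg: float
    age_class: str  # "subadult" | "adult"
    sounder_size: int

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"{self.animal_id}: mass_kg must be positive")
        if self.sounder_size < 1:
            raise ValueError(f"{self.animal_id}: sounder_size must be >= 1")
        if self.age_class not in ("subadult", "adult"):
            raise ValueError(f"{self.animal_id}: bad age_class {self.age_class!r}")


@dataclass(frozen=True)
class CohortPeriods:
    """Temporal configuration for one cohort.

    ``range_start``/``range_end`` bound the tracking range (end inclusive, as
    dates); the season window is the sub-range used for the season-long UD.
    Week blocks are anchored at ``week_anchor`` (default: range start).
    Date boundaries are interpreted as local midnight shifted by
    ``utc_offset_hours``.
    """

    range_start: date
    range_end: date
    season_start: date
    season_end: date
    week_anchor: date | None = None
    utc_offset_hours: float = 0.0

    def _dt(self, d: date) -> datetime:
        return datetime(d.year, d.month, d.day, tzinfo=timezone.utc) - timedelta(
            hours=self.utc_offset_hours
        )

    @property
    def range_interval(self) -> tuple[datetime, datetime]:
        # inclusive end date -> exclusive instant at next midnight
        return self._dt(self.range_start), self._dt(self.range_end + timedelta(days=1))

    @property
    def season_interval(self) -> tuple[datetime, datetime]:
        return self._dt(self.season_start), self._dt(self.season_end + timedelta(days=1))

    @property
    def anchor_dt(self) -> datetime:
        return self._dt(self.week_anchor or self.range_start)


#: Default temporal design of the two tracking cohorts.
DEFAULT_COHORTS: dict[int, CohortPeriods] = {
    2014: CohortPeriods(
        range_start=date(2014, 3, 27),
        range_end=date(2014, 7, 12),
        season_start=date(2014, 3, 27),
        season_end=date(2014, 7, 12),
    ),
    2016: CohortPeriods(
        range_start=date(2016, 1, 22),
        range_end=date(2016, 7, 31),
        season_start=date(2016, 3, 27),
        season_end=date(2016, 7, 12),
    ),
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(
    path,
    *,
    id_col: str = "id",
    time_col: str = "timestamp",
    x_col: str = "x",
    y_col: str = "y",
    cohort_col: str = "cohort",
    sep: str = ",",
) -> list[Trajectory]:
    """Read delimited telemetry into one :class:`Trajectory` per animal.

    Exact duplicate records (same id, timestamp and coordinates) are collapsed
    to the first occurrence with a warning; duplicate (id, timestamp) pairs
    with *different* coordinates raise, listing the offending rows.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, time_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"telemetry file {path}: missing column {col!r}")
    df = df.copy()
    df["_t"] = pd.to_datetime(df[time_col], utc=True, format="ISO8601")

    dup_key = df.duplicated(subset=[id_col, "_t"], keep=False)
    if dup_key.any():
        exact = df.duplicated(subset=[id_col, "_t", x_col, y_col], keep="first")
        # rows sharing (id, t) but not collapsible as exact duplicates:
        grp = df[dup_key].groupby([id_col, "_t"])
        bad_rows: list[int] = []
        for _, g in grp:
            if g[[x_col, y_col]].round(9).drop_duplicates().shape[0] > 1:
                bad_rows.extend(g.index.tolist())
        if bad_rows:
            raise ValueError(
                "conflicting coordinates at duplicated (id, timestamp) rows: "
                f"{sorted(bad_rows)}"
            )
        n_before = len(df)
        df = df[~exact]
        log.warning(
            "collapsed %d exact duplicate telemetry records", n_before - len(df)
        )

    out: list[Trajectory] = []
    for animal, g in df.groupby(id_col, sort=True):
        g = g.sort_values("_t")
        cohort = int(g[cohort_col].iloc[0]) if cohort_col in g.columns else int(
            g["_t"].dt.year.iloc[0]
        )
        out.append(
            Trajectory(
                animal_id=str(animal),
                cohort_year=cohort,
                times=(g["_t"].astype("int64") // 10**9).to_numpy(),
                x=g[x_col].to_numpy(float),
                y=g[y_col].to_numpy(float),
            )
        )
    return out


def write_tracks(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories in the delimited format :func:`read_tracks` reads."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.animal_id,
                    "cohort": tr.cohort_year,
                    "timestamp": pd.to_datetime(tr.times, unit="s", utc=True).strftime(
                        "%Y-%m-%dT%H:%M:%SZ"
                    ),
                    "x": tr.x,
                    "y": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_polygons(path) -> StudyPolygons:
    """Load study polygons from a GeoJSON FeatureCollection.

    Features are identified by a ``name`` property among ``landfill``,
    ``waste_cells`` and ``habitat_blhw``; coordinates are planar metres.
    """
    with open(path) as fh:
        gj = json.load(fh)
    geoms: dict[str, BaseGeometry] = {}
    for feat in gj.get("features", []):
        name = feat.get("properties", {}).get("name")
        if name:
            geoms[name] = _shapely_shape(feat["geometry"])
    if "landfill" not in geoms or "waste_cells" not in geoms:
        raise ValueError(f"{path}: needs 'landfill' and 'waste_cells' features")
    return StudyPolygons(
        landfill=geoms["landfill"],
        waste_cells=geoms["waste_cells"],
        habitat_blhw=geoms.get("habitat_blhw"),
    )


def read_attributes(path) -> dict[str, AnimalAttributes]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        a = AnimalAttributes(
            animal_id=str(row["animal_id"]),
            mass_kg=float(row["mass_kg"]),
            age_class=str(row["age_class"]),
            sounder_size=int(row["sounder_size"]),
        )
        out[a.animal_id] = a
    return out


# ---------------------------------------------------------------------------
# Temporal partitioning
# ---------------------------------------------------------------------------

def _month_periods(cfg: CohortPeriods) -> list[PeriodSpec]:
    """Calendar months fully contained in the cohort's tracking range."""
    lo, hi = cfg.range_interval
    periods = []
    y, m = lo.year, lo.month
    while True:
        m_start = cfg._dt(date(y, m, 1))
        ny, nm = (y + 1, 1) if m == 12 else (y, m + 1)
        m_end = cfg._dt(date(ny, nm, 1))
        if m_start > hi:
            break
        if m_start >= lo and m_end <= hi:
            periods.append(
                PeriodSpec("month", f"{y:04d}-{m:02d}", m_start, m_end)
            )
        y, m = ny, nm
    return periods


def _week_periods(cfg: CohortPeriods) -> list[PeriodSpec]:
    """Consecutive 7-day blocks from the anchor.

    The trailing remainder shorter than a week is discarded together with the
    complete week immediately preceding it, so every retained week is followed
    by at least a week of telemetry; this reproduces the weekly-period counts
    of the study design (14 weeks for a 27 Mar-12 Jul range, 26 for
    22 Jan-31 Jul).  When the range is an exact multiple of 7 days all blocks
    are kept.
    """
    anchor = cfg.anchor_dt
    _, hi = cfg.range_interval
    total_days = (hi - anchor).days
    n_full = total_days // 7
    n_weeks = n_full if total_days % 7 == 0 else max(n_full - 1, 0)
    periods = []
    for k in range(n_weeks):
        start = anchor + timedelta(days=7 * k)
        end = start + timedelta(days=7)
        periods.append(
            PeriodSpec("week", f"{start.date().isoformat()}-W{k + 1:02d}", start, end)
        )
    return periods


def list_periods(cfg: CohortPeriods, scale: str) -> list[PeriodSpec]:
    """All periods of one scale for a cohort configuration."""
    if scale == "season":
        lo, hi = cfg.season_interval
        label = f"{lo.year:04d}-season"
        return [PeriodSpec("season", label, lo, hi)]
    if scale == "month":
        return _month_periods(cfg)
    if scale == "week":
        return _week_periods(cfg)
    raise ValueError(f"unknown scale {scale!r}")


def partition_periods(
    traj: Trajectory,
    scale: str,
    config: dict[int, CohortPeriods] | None = None,
    *,
    min_fixes: int = 24,
) -> list[tuple[PeriodSpec, Trajectory]]:
    """Split a trajectory into (period, sub-trajectory) pairs at one scale.

    Periods whose sub-trajectory holds fewer than ``min_fixes`` fixes are
    dropped with a log entry; an entirely empty result yields a warning and an
    empty list.
    """
    config = config or DEFAULT_COHORTS
    if traj.cohort_year not in config:
        raise ValueError(f"no period configuration for cohort {traj.cohort_year}")
    cfg = config[traj.cohort_year]
    out: list[tuple[PeriodSpec, Trajectory]] = []
    for period in list_periods(cfg, scale):
        sub = traj.slice_window(period.start_s, period.end_s)
        if sub is None or len(sub) < min_fixes:
            n = 0 if sub is None else len(sub)
            log.info(
                "dropping %s %s for %s: %d fixes < min_fixes=%d",
                scale, period.label, traj.animal_id, n, min_fixes,
            )
            continue
        out.append((period, sub))
    if not out:
        log.warning("no %s periods retained for %s", scale, traj.animal_id)
    return out


# ---------------------------------------------------------------------------
# Temporal alignment of dyads
# ---------------------------------------------------------------------------

def match_simultaneous(
    a: Trajectory, b: Trajectory, time_tol: float = 600.0
) -> np.ndarray:
    """One-to-one temporal matching of two trajectories.

    Returns an (m, 2) integer array of (index-in-a, index-in-b) pairs with
    |Δt| strictly below ``time_tol`` seconds.  Matching is greedy on |Δt|
    (smallest first; ties broken by the earlier fix), each fix used at most
    once, which makes the pair count symmetric in the argument order.  Only
    the temporal criterion is applied; spatial thresholds are applied by the
    interaction indices downstream.
    """
    if time_tol <= 0:
        raise ValueError("time_tol must be positive")
    ta, tb = a.times, b.times
    lo = np.searchsorted(tb, ta - int(np.ceil(time_tol)), side="left")
    hi = np.searchsorted(tb, ta + int(np.ceil(time_tol)), side="right")
    cand: list[tuple[float, int, int, int]] = []
    for i in range(len(ta)):
        for j in range(int(lo[i]), int(hi[i])):
            dt = abs(int(ta[i]) - int(tb[j]))
            if dt < time_tol:
                cand.append((dt, int(ta[i]), int(tb[j]), i * len(tb) + j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for dt, _, _, code in cand:
        i, j = divmod(code, len(tb))
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)
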