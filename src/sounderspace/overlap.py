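"""Isopleth home ranges / core areas and dyadic overlap statistics.

Home ranges are the 95% UD isopleth, core areas the 50% isopleth.  Dyads are
unordered pairs of animals whose 95% isopleths intersect in any period of any
scale; for each dyad the directional 2D proportional overlap and the volume
of intersection (VI = sum of cell-wise minima of the two normalized UDs) are
computed, then aggregated per sow and period as the modeling responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dbbmm import RasterGrid, UtilizationDistribution
from .tracks import PeriodSpec

log = logging.getLogger(__name__)

HOME_RANGE_LEVEL = 0.95
CORE_AREA_LEVEL = 0.50


@dataclass
class IsoplethRegion:
    """Smallest cell set whose cumulative UD mass reaches ``level``."""

    animal_id: str
    period: PeriodSpec | None
    level: float
    grid: RasterGrid
    cells: np.ndarray  # sorted flat cell indices (row-major)

    @property
    def area_ha(self) -> float:
        return len(self.cells) * self.grid.cell_area_ha

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.nrows * self.grid.ncols, dtype=bool)
        m[self.cells] = True
        return m.reshape(self.grid.nrows, self.grid.ncols)


@dataclass(frozen=True)
class Dyad:
    """Unordered pair of neighbouring animals (ids stored sorted)."""

    animal_a: str
    animal_b: str

    def __post_init__(self) -> None:
        if self.animal_a == self.animal_b:
            raise ValueError("dyad members must differ")
        if self.animal_a > self.animal_b:
            a, b = self.animal_b, self.animal_a
            object.__setattr__(self, "animal_a", a)
            object.__setattr__(self, "animal_b", b)

    def __iter__(self):
        return iter((self.animal_a, self.animal_b))


@dataclass
class OverlapRecord:
    dyad: Dyad
    scale: str
    period_label: str
    ud_level: float
    overlap_2d_ab: float  # proportion of A's region shared with B
    overlap_2d_ba: float
    vi: float


def extract_isopleth(ud: UtilizationDistribution, level: float) -> IsoplethRegion:
    """Cells sorted by density descending, included until cumulative >= level.

    Ties at the inclusion boundary are broken by (row, col) lexicographic
    order so the region is deterministic.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    flat = ud.density.ravel()
    rows, cols = np.divmod(np.arange(flat.size), ud.grid.ncols)
    order = np.lexsort((cols, rows, -flat))
    csum = np.cumsum(flat[order])
    m = int(np.searchsorted(csum, level - 1e-12)) + 1
    m = min(m, int((flat > 0).sum()) or 1)
    cells = np.sort(order[:m])
    return IsoplethRegion(
        animal_id=ud.animal_id, period=ud.period, level=level, grid=ud.grid,
        cells=cells,
    )


def _check_same_grid(g1: RasterGrid, g2: RasterGrid) -> None:
    if g1 != g2:
        raise ValueError("regions/UDs live on different grids; no resampling in core")


def overlap_2d(a: IsoplethRegion, b: IsoplethRegion) -> tuple[float, float]:
    """Directional proportional area overlap (prop of A in B, prop of B in A)."""
    _check_same_grid(a.grid, b.grid)
    inter = np.intersect1d(a.cells, b.cells, assume_unique=True).size
    return inter / len(a.cells), inter / len(b.cells)


def volume_of_intersection(
    ud_a: UtilizationDistribution,
    ud_b: UtilizationDistribution,
    level: float | None = None,
) -> float:
    """VI = sum of cell-wise minima of two unit-mass UDs.

    With ``level`` given, each UD is first truncated to its own isopleth at
    that level and renormalized to unit mass (home-range / core-area VI).
    """
    _check_same_grid(ud_a.grid, ud_b.grid)
    pa, pb = ud_a.density, ud_b.density
    if level is not None:
        pa = _truncate_renorm(ud_a, level)
        pb = _truncate_renorm(ud_b, level)
    return float(np.minimum(pa, pb).sum())


def _truncate_renorm(ud: UtilizationDistribution, level: float) -> np.ndarray:
    region = extract_isopleth(ud, level)
    out = np.zeros_like(ud.density)
    mask = region.mask()
    out[mask] = ud.density[mask]
    return out / out.sum()


def find_dyads(regions: Iterable[IsoplethRegion]) -> list[Dyad]:
    """Dyads: animal pairs whose 95% isopleths intersect in any period.

    ``regions`` should span every period of every scale for one cohort; the
    resulting dyad set is then fixed for all analyses of that cohort.
    """
    by_animal: dict[str, list[IsoplethRegion]] = {}
    for r in regions:
        by_animal.setdefault(r.animal_id, []).append(r)
    dyads = []
    for a, b in combinations(sorted(by_animal), 2):
        hit = False
        for ra in by_animal[a]:
            for rb in by_animal[b]:
                _check_same_grid(ra.grid, rb.grid)
                if np.intersect1d(ra.cells, rb.cells, assume_unique=True).size:
                    hit = True
                    break
            if hit:
                break
        if hit:
            dyads.append(Dyad(a, b))
    return dyads


def isopleth_to_geojson(region: IsoplethRegion) -> dict:
    """GeoJSON Feature with the region's cells dissolved to a (multi)polygon."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    g = region.grid
    rows, cols = np.divmod(region.cells, g.ncols)
    cells = [
        box(g.x0 + c * g.cell, g.y0 + r * g.cell,
            g.x0 + (c + 1) * g.cell, g.y0 + (r + 1) * g.cell)
        for r, c in zip(rows, cols)
    ]
    return {
        "type": "Feature",
        "properties": {
            "animal_id": region.animal_id,
            "level": region.level,
            "period": region.period.label if region.period else None,
            "area_ha": region.area_ha,
        },
        "geometry": mapping(unary_union(cells)),
    }


def overlap_records_frame(records: Sequence[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_a": [r.dyad.animal_a for r in records],
            "animal_b": [r.dyad.animal_b for r in records],
            "scale": [r.scale for r in records],
            "period": [r.period_label for r in records],
            "ud_level": [r.ud_level for r in records],
            "overlap_2d_ab": [r.overlap_2d_ab for r in records],
            "overlap_2d_ba": [r.overlap_2d_ba for r in records],
            "vi": [r.vi for r in records],
        }
    )


def aggregate_by_sow(records: Sequence[OverlapRecord]) -> pd.DataFrame:
    """Mean VI and mean sow-directional 2D overlap per (sow, period, scale, level).

    A sow in several dyads within one period contributes the mean of her
    dyad values; the 2D response is directional (proportion of *her* region
    shared with each neighbour).  Sows with no dyads in a period are simply
    absent from the table.
    """
    rows = []
    for r in records:
        rows.append((r.dyad.animal_a, r.scale, r.period_label, r.ud_level,
                     r.overlap_2d_ab, r.vi))
        rows.append((r.dyad.animal_b, r.scale, r.period_label, r.ud_level,
                     r.overlap_2d_ba, r.vi))
    if not rows:
        return pd.DataFrame(
            columns=["animal_id", "scale", "period", "ud_level",
                     "overlap_2d", "vi"]
        )
    df = pd.DataFrame(
        rows, columns=["animal_id", "scale", "period", "ud_level",
                       "overlap_2d", "vi"]
    )
    out = (
        df.groupby(["animal_id", "scale", "period", "ud_level"], as_index=False)
        .mean(numeric_only=True)
        .sort_values(["animal_id", "scale", "period", "ud_level"])
        .reset_index(drop=True)
    )
    return out


def compute_overlap_records(
    uds: Mapping[tuple[str, str, str], UtilizationDistribution],
    dyads: Sequence[Dyad],
    levels: Sequence[float] = (HOME_RANGE_LEVEL, CORE_AREA_LEVEL),
) -> list[OverlapRecord]:
    """Overlap records for every dyad x (scale, period) x UD level.

    ``uds`` maps (animal_id, scale, period_label) to the UD; a dyad-period is
    evaluated only when both members have a UD there.
    """
    by_scale_period: dict[tuple[str, str], dict[str, UtilizationDistribution]] = {}
    for (animal, scale, period), ud in uds.items():
        by_scale_period.setdefault((scale, period), {})[animal] = ud
    records: list[OverlapRecord] = []
    for (scale, period), animal_uds in sorted(by_scale_period.items()):
        iso_cache: dict[tuple[str, float], IsoplethRegion] = {}
        for dyad in dyads:
            a, b = dyad.animal_a, dyad.animal_b
            if a not in animal_uds or b not in animal_uds:
                continue
            for level in levels:
                for animal in (a, b):
                    if (animal, level) not in iso_cache:
                        iso_cache[(animal, level)] = extract_isopleth(
                            animal_uds[animal], level
                        )
                pab, pba = overlap_2d(iso_cache[(a, level)], iso_cache[(b, level)])
                vi = volume_of_intersection(
                    animal_uds[a], animal_uds[b], level=level
                )
                records.append(
                    OverlapRecord(
                        dyad=dyad, scale=scale, period_label=period,
                        ud_level=level, overlap_2d_ab=pab, overlap_2d_ba=pba,
                        vi=vi,
                    )
                )
    return records
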