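"""Dynamic Brownian bridge movement model (dBBMM) utilization distributions.

The dBBMM conditions a Brownian bridge on consecutive GPS fixes and lets the
Brownian motion variance sigma^2_m (m^2/s) vary along the track.  sigma^2_m is
estimated by sliding a window over the track (default 29 fixes, margin 11)
and maximising, within each window, the leave-one-out likelihood in which
every odd-indexed interior fix is predicted by the bridge spanning its
even-indexed neighbours; a single-variance model competes against
one-change-point models by BIC, and per-fix estimates average the selected
segment values over all windows covering the fix in their margin interior.

The utilization distribution integrates the bridge kernels of consecutive fix
pairs on a fixed metric grid (default 50 m cells) with an isotropic GPS
location error (default 20 m standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tracks import PeriodSpec, Trajectory

log = logging.getLogger(__name__)

#: log10 search bounds for sigma^2_m (m^2/s)
_LOG10_SIG2_LO, _LOG10_SIG2_HI = -8.0, 4.0
#: grid resolution used before parabolic refinement (points per decade)
_GRID_PER_DECADE = 8


@dataclass(frozen=True)
class ErrorModel:
    """Isotropic GPS location error: per-axis standard deviation in metres."""

    delta: float = 20.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("location-error SD must be >= 0")


@dataclass(frozen=True)
class RasterGrid:
    """Metric raster; (x0, y0) is the lower-left cell corner, multiples of cell."""

    x0: float
    y0: float
    cell: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.ncols < 1 or self.nrows < 1:
            raise ValueError("invalid grid geometry")

    @property
    def cell_area_ha(self) -> float:
        return self.cell * self.cell / 1e4

    @property
    def xs(self) -> np.ndarray:
        """x coordinates of cell centres, length ncols."""
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell

    @property
    def ys(self) -> np.ndarray:
        """y coordinates of cell centres, length nrows (row 0 at the bottom)."""
        return self.y0 + (np.arange(self.nrows) + 0.5) * self.cell

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmax = self.x0 + self.ncols * self.cell
        ymax = self.y0 + self.nrows * self.cell
        return (x >= self.x0) & (x < xmax) & (y >= self.y0) & (y < ymax)


@dataclass
class MotionVarianceProfile:
    """Per-fix Brownian motion variance sigma^2_m (m^2/s)."""

    sigma2: np.ndarray
    window: int
    margin: int

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if not np.isfinite(self.sigma2).all() or (self.sigma2 < 0).any():
            raise ValueError("sigma^2_m must be finite and non-negative")


@dataclass
class UtilizationDistribution:
    """Gridded probability surface for one animal x period; sums to one."""

    animal_id: str
    period: PeriodSpec | None
    grid: RasterGrid
    density: np.ndarray  # (nrows, ncols), row 0 at the bottom

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("density shape does not match grid")
        if (self.density < 0).any():
            raise ValueError("negative UD mass")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError("UD mass does not sum to one")


def make_grid(
    trajectories: Sequence[Trajectory],
    cell: float = 50.0,
    buffer: float = 1000.0,
    override: RasterGrid | None = None,
) -> RasterGrid:
    """Grid covering every fix of the given trajectories plus a buffer.

    The origin is snapped down to a multiple of the cell size so grids built
    for the same cohort align cell-for-cell.  An ``override`` grid is
    returned unchanged after checking that it covers every fix.
    """
    if not trajectories:
        raise ValueError("make_grid needs at least one trajectory")
    if override is not None:
        for tr in trajectories:
            if not override.contains(tr.x, tr.y).all():
                raise ValueError(f"override grid does not cover {tr.animal_id!r}")
        return override
    if cell <= 0 or buffer < 0:
        raise ValueError("cell must be > 0 and buffer >= 0")
    xs = np.concatenate([t.x for t in trajectories])
    ys = np.concatenate([t.y for t in trajectories])
    x0 = np.floor((xs.min() - buffer) / cell) * cell
    y0 = np.floor((ys.min() - buffer) / cell) * cell
    ncols = int(np.ceil((xs.max() + buffer - x0) / cell))
    nrows = int(np.ceil((ys.max() + buffer - y0) / cell))
    return RasterGrid(x0=float(x0), y0=float(y0), cell=float(cell),
                      ncols=max(ncols, 1), nrows=max(nrows, 1))


def bridge_variance(t_frac, T, sigma2_m, delta_start, delta_end):
    """Variance (m^2, per axis) of the Brownian bridge at fractional time.

    ``t_frac`` is alpha in [0, 1] along a bridge of duration ``T`` seconds
    with motion variance ``sigma2_m`` and location-error SDs at the two
    anchoring fixes::

        T * a * (1 - a) * sigma2_m + (1 - a)^2 * delta_start^2 + a^2 * delta_end^2
    """
    a = np.asarray(t_frac, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("t_frac must lie in [0, 1]")
    if np.any(np.asarray(T) <= 0):
        raise ValueError("bridge duration must be positive")
    if np.any(np.asarray(sigma2_m) < 0) or np.any(np.asarray(delta_start) < 0) or np.any(
        np.asarray(delta_end) < 0
    ):
        raise ValueError("variance inputs must be non-negative")
    return (
        T * a * (1.0 - a) * sigma2_m
        + (1.0 - a) ** 2 * np.asarray(delta_start) ** 2
        + a**2 * np.asarray(delta_end) ** 2
    )


# ---------------------------------------------------------------------------
# Motion-variance estimation
# ---------------------------------------------------------------------------

def _loo_terms(traj: Trajectory, delta: float):
    """Per-interior-fix leave-one-out quantities.

    Fix k (1..n-2) is predicted from fixes k-1 and k+1: the likelihood is an
    isotropic bivariate normal centred on the linear interpolation at the
    fix's fractional time, with per-axis variance ``a_k * sigma2 + b_k`` where
    ``a_k = T alpha (1-alpha)`` and ``b_k`` collects the neighbours'
    interpolated location error plus the predicted fix's own error delta^2.
    Returns (a, b, d2) arrays of length n-2, d2 the squared 2-D residual.
    """
    t = traj.times.astype(float)
    T = t[2:] - t[:-2]
    alpha = (t[1:-1] - t[:-2]) / T
    a = T * alpha * (1.0 - alpha)
    b = ((1.0 - alpha) ** 2 + alpha**2) * delta**2 + delta**2
    mx = (1.0 - alpha) * traj.x[:-2] + alpha * traj.x[2:]
    my = (1.0 - alpha) * traj.y[:-2] + alpha * traj.y[2:]
    d2 = (traj.x[1:-1] - mx) ** 2 + (traj.y[1:-1] - my) ** 2
    return a, b, d2


def _loglik_grid(a, b, d2, sig2_grid):
    """Log-likelihood matrix L[g, k] of each LOO point under each sigma^2."""
    v = a[None, :] * sig2_grid[:, None] + b[None, :]
    return -np.log(2.0 * np.pi * v) - d2[None, :] / (2.0 * v)


def _refine(log10_grid, ll, g):
    """Parabolic refinement of the grid argmax on the log10 scale."""
    if 0 < g < len(log10_grid) - 1:
        y0, y1, y2 = ll[g - 1], ll[g], ll[g + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            step = log10_grid[1] - log10_grid[0]
            return 10.0 ** (log10_grid[g] + shift * step)
    return 10.0 ** log10_grid[g]


def static_motion_variance(traj: Trajectory, err: ErrorModel) -> float:
    """Single maximum-likelihood sigma^2_m over the whole track (odd LOO fixes)."""
    a, b, d2 = _loo_terms(traj, err.delta)
    sel = np.arange(len(a)) % 2 == 0  # interior index k = 1, 3, 5, ...
    a, b, d2 = a[sel], b[sel], d2[sel]
    log10_grid = np.linspace(
        _LOG10_SIG2_LO, _LOG10_SIG2_HI,
        int((_LOG10_SIG2_HI - _LOG10_SIG2_LO) * _GRID_PER_DECADE) + 1,
    )
    L = _loglik_grid(a, b, d2, 10.0**log10_grid).sum(axis=1)
    g = int(np.argmax(L))
    return _refine(log10_grid, L, g)


def estimate_motion_variance(
    traj: Trajectory,
    err: ErrorModel | None = None,
    window: int = 29,
    margin: int = 11,
) -> MotionVarianceProfile:
    """Per-fix sigma^2_m by the windowed change-point scheme.

    Within each window the single-variance model competes by BIC against every
    one-change-point split leaving at least ``margin`` fixes on each side;
    each fix accumulates the variance of the segment covering it from every
    window containing it in its margin interior, and the final estimate is
    the mean of the accumulated values.  Fixes never covered inherit the
    nearest covered fix's value.  Tracks shorter than the window fall back to
    a single global maximum-likelihood value.
    """
    err = err or ErrorModel()
    n = len(traj)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if margin < 3:
        raise ValueError("margin must be >= 3")
    if window < 2 * margin + 1:
        raise ValueError("window must be >= 2*margin + 1")
    if n < window:
        log.info(
            "track %s shorter than window (%d < %d): static sigma^2_m fallback",
            traj.animal_id, n, window,
        )
        s2 = static_motion_variance(traj, err)
        return MotionVarianceProfile(np.full(n, s2), window=window, margin=margin)

    a, b, d2 = _loo_terms(traj, err.delta)  # interior fixes 1..n-2
    log10_grid = np.linspace(
        _LOG10_SIG2_LO, _LOG10_SIG2_HI,
        int((_LOG10_SIG2_HI - _LOG10_SIG2_LO) * _GRID_PER_DECADE) + 1,
    )
    sig2_grid = 10.0**log10_grid
    L = _loglik_grid(a, b, d2, sig2_grid)  # (G, n-2)

    # cumulative sums per parity of the *global fix index* (interior k+1)
    # LOO points used by window starting at i are global fixes i+1, i+3, ...
    # i+window-2; all share parity (i+1) % 2.
    # parity arrays index interior points: interior j covers global fix j+1.
    par = [np.flatnonzero((np.arange(1, n - 1) % 2) == p) for p in (0, 1)]
    cum = [
        np.concatenate([np.zeros((L.shape[0], 1)), np.cumsum(L[:, idx], axis=1)], axis=1)
        for idx in par
    ]
    # map: global fix g (interior) -> ordinal within its parity ordering
    ordinal = np.full(n, -1, dtype=int)
    for p in (0, 1):
        ordinal[par[p] + 1] = np.arange(len(par[p]))

    m_pts = (window - 1) // 2  # LOO points per window
    log_m = np.log(m_pts)
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    c_lo, c_hi = margin, window - 1 - margin  # local change-point candidates

    for i in range(n - window + 1):
        p = (i + 1) % 2
        C = cum[p]
        first = ordinal[i + 1]  # ordinal of first LOO point
        lastp1 = first + m_pts
        full = C[:, lastp1] - C[:, first]
        g1 = int(np.argmax(full))
        best_bic = -2.0 * full[g1] + log_m
        best = ("single", g1)
        for c in range(c_lo, c_hi + 1):
            m1 = (c + 1) // 2  # LOO points with local odd index <= c
            if m1 == 0 or m1 == m_pts:
                continue
            left = C[:, first + m1] - C[:, first]
            right = C[:, lastp1] - C[:, first + m1]
            gl = int(np.argmax(left))
            gr = int(np.argmax(right))
            bic = -2.0 * (left[gl] + right[gr]) + 2.0 * log_m
            if bic < best_bic:
                best_bic = bic
                best = ("split", c, gl, gr, left, right)
        interior = np.arange(margin, window - margin)  # local margin interior
        if best[0] == "single":
            s2 = _refine(log10_grid, full, best[1])
            acc[i + interior] += s2
        else:
            _, c, gl, gr, left, right = best
            s2l = _refine(log10_grid, left, gl)
            s2r = _refine(log10_grid, right, gr)
            vals = np.where(interior <= c, s2l, s2r)
            acc[i + interior] += vals
        cnt[i + interior] += 1

    covered = cnt > 0
    sigma2 = np.zeros(n)
    sigma2[covered] = acc[covered] / cnt[covered]
    if not covered.all():
        idx = np.flatnonzero(covered)
        nearest = idx[
            np.argmin(np.abs(np.arange(n)[:, None] - idx[None, :]), axis=1)
        ]
        fill = ~covered
        sigma2[fill] = sigma2[nearest[fill]]
    return MotionVarianceProfile(sigma2, window=window, margin=margin)


# ---------------------------------------------------------------------------
# UD estimation
# ---------------------------------------------------------------------------

def estimate_ud(
    traj: Trajectory,
    profile: MotionVarianceProfile,
    grid: RasterGrid,
    err: ErrorModel | None = None,
    *,
    n_int: int = 10,
    max_gap: float = 8 * 3600.0,
    trunc_sd: float = 4.0,
    animal_id: str | None = None,
    period: PeriodSpec | None = None,
) -> UtilizationDistribution:
    """Integrate the bridge kernels of a track into a normalized UD.

    Consecutive-fix gaps above ``max_gap`` seconds are not bridged.  Each
    retained pair contributes ``n_int`` isotropic Gaussian kernels at the
    midpoints of equal time sub-intervals, weighted by sub-interval duration,
    truncated beyond ``trunc_sd`` standard deviations.
    """
    err = err or ErrorModel()
    if len(profile.sigma2) != len(traj):
        raise ValueError("motion-variance profile length does not match track")
    t = traj.times.astype(float)
    dt = np.diff(t)
    keep = dt <= max_gap
    if not keep.any():
        raise ValueError("no usable bridges: every consecutive gap exceeds max_gap")

    density = np.zeros((grid.nrows, grid.ncols))
    xs0, ys0, cell = grid.x0, grid.y0, grid.cell
    alphas = (np.arange(n_int) + 0.5) / n_int
    sig2_pair = 0.5 * (profile.sigma2[:-1] + profile.sigma2[1:])

    for k in np.flatnonzero(keep):
        T = dt[k]
        w = T / n_int
        var = bridge_variance(alphas, T, sig2_pair[k], err.delta, err.delta)
        var = np.maximum(var, 1e-12)
        mx = (1.0 - alphas) * traj.x[k] + alphas * traj.x[k + 1]
        my = (1.0 - alphas) * traj.y[k] + alphas * traj.y[k + 1]
        sd = np.sqrt(var)
        for j in range(n_int):
            r = trunc_sd * sd[j]
            c0 = max(int(np.floor((mx[j] - r - xs0) / cell)), 0)
            c1 = min(int(np.ceil((mx[j] + r - xs0) / cell)), grid.ncols)
            r0 = max(int(np.floor((my[j] - r - ys0) / cell)), 0)
            r1 = min(int(np.ceil((my[j] + r - ys0) / cell)), grid.nrows)
            if c0 >= c1 or r0 >= r1:
                continue
            cx = xs0 + (np.arange(c0, c1) + 0.5) * cell
            cy = ys0 + (np.arange(r0, r1) + 0.5) * cell
            gx = np.exp(-((cx - mx[j]) ** 2) / (2.0 * var[j]))
            gy = np.exp(-((cy - my[j]) ** 2) / (2.0 * var[j]))
            gx[np.abs(cx - mx[j]) > r] = 0.0
            gy[np.abs(cy - my[j]) > r] = 0.0
            density[r0:r1, c0:c1] += (w / (2.0 * np.pi * var[j])) * np.outer(gy, gx)

    total = density.sum()
    if total <= 0:
        raise ValueError("UD mass vanished: track outside the grid?")
    density /= total
    return UtilizationDistribution(
        animal_id=animal_id or traj.animal_id,
        period=period,
        grid=grid,
        density=density,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def ud_to_ascii_grid(ud: UtilizationDistribution) -> str:
    """ESRI ASCII grid serialisation (row 0 of the text = top of the grid)."""
    g = ud.grid
    header = (
        f"ncols {g.ncols}\nnrows {g.nrows}\nxllcorner {g.x0}\nyllcorner {g.y0}\n"
        f"cellsize {g.cell}\nNODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(f"{v:.8e}" for v in row) for row in ud.density[::-1]
    )
    return header + body + "\n"


def ud_to_frame(ud: UtilizationDistribution):
    """Tidy (cell_x, cell_y, density) table of the non-zero cells."""
    import pandas as pd

    rr, cc = np.nonzero(ud.density)
    return pd.DataFrame(
        {
            "cell_x": ud.grid.x0 + (cc + 0.5) * ud.grid.cell,
            "cell_y": ud.grid.y0 + (rr + 0.5) * ud.grid.cell,
            "density": ud.density[rr, cc],
        }
    )
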