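from __future__ import annotations

import numpy as np
import pytest

from sounderspace.dbbmm import RasterGrid, UtilizationDistribution
from sounderspace.tracks import Trajectory


def make_traj(times, x, y, animal_id="a", cohort=2016) -> Trajectory:
    return Trajectory(
        animal_id=animal_id, cohort_year=cohort,
        times=np.asarray(times, dtype=np.int64),
        x=np.asarray(x, float), y=np.asarray(y, float),
    )


def make_ud(density, cell=50.0, animal_id="a") -> UtilizationDistribution:
    density = np.asarray(density, float)
    density = density / density.sum()
    grid = RasterGrid(x0=0.0, y0=0.0, cell=cell,
                      ncols=density.shape[1], nrows=density.shape[0])
    return UtilizationDistribution(
        animal_id=animal_id, period=None, grid=grid, density=density
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ud(rng, shape=(20, 20), concentration=3.0, animal_id="a"):
    """A random patchy UD: exponentiated Gaussian noise, normalized."""
    z = np.exp(concentration * rng.normal(size=shape))
    return make_ud(z, animal_id=animal_id)


def brownian_track(rng, n=300, dt=7200, sigma2=0.4, delta=20.0, animal_id="bm"):
    steps = rng.normal(scale=np.sqrt(sigma2 * dt), size=(n, 2))
    xy = np.cumsum(steps, axis=0) + rng.normal(scale=delta, size=(n, 2))
    return make_traj(np.arange(n) * dt, xy[:, 0], xy[:, 1], animal_id=animal_id)
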