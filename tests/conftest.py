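import numpy as np
import pytest

from ringmaps import presets
from ringmaps.meanfield import Grid
from ringmaps.phase import solve_fixed_point


@pytest.fixture(scope="session")
def grid():
    """Default quadrature grid for the test suite (desk scale)."""
    return Grid(n_theta=128, n_phi=65)


@pytest.fixture(scope="session")
def fine_grid():
    return Grid(n_theta=256, n_phi=129)


@pytest.fixture(scope="session")
def single_ring_fp(grid):
    return solve_fixed_point(presets.SINGLE_RING, grid=grid)


@pytest.fixture(scope="session")
def double_ring_fp(grid):
    return solve_fixed_point(presets.DOUBLE_RING, grid=grid)


@pytest.fixture(scope="session")
def cylinder_fp(grid):
    return solve_fixed_point(presets.CYLINDER_SHALLOW, grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
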