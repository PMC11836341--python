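import numpy as np
import pytest

from divdrought.raster_grid import ForestMask, GridSpec, MaskedRaster
from divdrought.synthetic_data import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid10():
    return GridSpec(10, 10)


@pytest.fixture
def all_forest():
    def make(grid):
        return ForestMask(grid, np.ones(grid.shape, bool))

    return make


@pytest.fixture
def full_raster():
    def make(grid, values):
        return MaskedRaster.full(grid, np.asarray(values, dtype=float))

    return make


@pytest.fixture
def small_cfg():
    """Small, fast synthetic domain used by unit tests (not the study-size
    domain of the acceptance suite)."""
    return SyntheticConfig(seed=7, n_rows=40, n_cols=40, n_scenes=1)
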