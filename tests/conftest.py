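import numpy as np
import pytest

from restpipe.core import BoldSeries, GridSpec, TissueMask
from restpipe.preprocess import binarize_gm
from restpipe.synthetic_cohort import gm_probability_map


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """Desk-scale grid used across tests (fast, even left-right axis)."""
    return GridSpec(shape=(10, 10, 6), voxel_size=(3.0, 3.0, 3.0), n_volumes=60)


@pytest.fixture
def default_grid():
    return GridSpec()


@pytest.fixture
def small_mask(small_grid):
    return binarize_gm(gm_probability_map(small_grid))


def make_bold(rng, shape=(6, 6, 4), T=60, tr=2.0):
    return BoldSeries(rng.standard_normal(shape + (T,)), tr=tr, affine=np.eye(4))


@pytest.fixture
def tiny_bold(rng):
    return make_bold(rng)


@pytest.fixture
def tiny_mask(tiny_bold):
    return TissueMask(np.ones(tiny_bold.spatial_shape, dtype=bool))
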