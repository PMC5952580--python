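import numpy as np
import pytest
from hypothesis import settings

import tvtomo as tt

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return tt.VolumeGrid(8, 8, 1, 0.5)


@pytest.fixture
def small_geom(small_grid):
    return tt.default_geometry(small_grid, num_proj=10, span=360.0, dim_proj=13)


@pytest.fixture(scope="session")
def phantom64():
    """Piecewise-constant 64x64 phantom used by the end-to-end tests."""
    spec = tt.PhantomSpec(
        kind="random_ellipsoids", dims=(64, 64, 1), voxel_size=0.5, n_objects=4, seed=7
    )
    return tt.make_phantom(spec)
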