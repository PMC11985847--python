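import numpy as np
import pytest

from fcnm.grids import make_grid
from fcnm.simulate import SimulationConfig, make_synthetic_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid3mm():
    """Small 3-mm isotropic grid with origin at world (0,0,0)."""
    return make_grid((10, 10, 10), (3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Fast simulation settings for module-level tests."""
    return SimulationConfig(
        shape=(12, 14, 12), n_subjects=6, n_timepoints=60, rng_seed=11
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_cfg):
    return make_synthetic_atlas(tiny_cfg)
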