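import numpy as np
import pytest

from strokecov.tbm import default_brain_mask
from strokecov.volume import VolumeMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mask():
    """Small spherical brain mask on a 16^3 grid, 2 mm voxels."""
    return default_brain_mask((16, 16, 16), 2.0)


@pytest.fixture
def toy_map():
    return VolumeMap(np.zeros((5, 5, 5)), 2.0)
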