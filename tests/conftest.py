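import numpy as np
import pytest

from rsdiag import Mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_mask_4x3x2():
    return Mask(np.ones((4, 3, 2), dtype=bool))


@pytest.fixture
def mask_186():
    """A 186-voxel mask on the 7x8x6 grid (the r=8 reduced grid size)."""
    rng = np.random.default_rng(7)
    flat = np.zeros(336, dtype=bool)
    flat[rng.choice(336, size=186, replace=False)] = True
    return Mask(flat.reshape((7, 8, 6)))
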