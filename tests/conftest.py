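import numpy as np
import pytest

from cogmap import HRFSpec, ScanGrid, VolumeGrid


@pytest.fixture
def hrf():
    return HRFSpec()


@pytest.fixture
def small_grid():
    """12³ grid at 4 mm centered on the origin."""
    affine = np.array(
        [[4.0, 0, 0, -22.0], [0, 4.0, 0, -22.0], [0, 0, 4.0, -22.0], [0, 0, 0, 1.0]]
    )
    return VolumeGrid(dims=(12, 12, 12), affine=affine)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
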