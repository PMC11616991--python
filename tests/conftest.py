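import numpy as np
import pytest

from oscillonet import VolumeImage, mni_grid


@pytest.fixture
def freq_grid():
    return np.arange(1.0, 100.0 + 1e-9, 0.5)


@pytest.fixture
def coarse_grid():
    """Small 8 mm MNI-like grid for fast volumetric tests."""
    return mni_grid(shape=(23, 27, 23), voxel_mm=8.0)


@pytest.fixture
def tiny_grid():
    """Minimal 2 mm grid centred on the origin."""
    affine = np.array(
        [
            [-2.0, 0, 0, 10.0],
            [0, 2.0, 0, -10.0],
            [0, 0, 2.0, -10.0],
            [0, 0, 0, 1.0],
        ]
    )
    return VolumeImage(np.zeros((11, 11, 11)), affine)
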