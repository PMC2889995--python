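import numpy as np
import pytest

from granuloc import SimParams, Stack, VoxelGeometry


@pytest.fixture
def geometry() -> VoxelGeometry:
    return VoxelGeometry(pixel_size_xy=90.0 / 512.0, z_interval=0.5, field_size_xy=90.0)


@pytest.fixture
def small_stack() -> Stack:
    rng = np.random.default_rng(7)
    geo = VoxelGeometry(pixel_size_xy=0.2, z_interval=0.5)
    channels = {
        "ch0": rng.integers(0, 256, size=(4, 16, 16)).astype(np.uint8),
        "ch1": rng.integers(0, 256, size=(4, 16, 16)).astype(np.uint8),
    }
    return Stack(channels=channels, geometry=geo)


@pytest.fixture
def quiet_sim_params() -> SimParams:
    """Small, fast simulation: 40 puncta, 2 channels, modest noise."""
    return SimParams(
        shape=(8, 128, 128), n_channels=2, n_puncta=40, coloc_fraction=0.2, seed=11
    )
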