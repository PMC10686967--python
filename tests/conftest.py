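import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alesim import VoxelGrid, default_samplers, make_synthetic_mask

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def desk_grid():
    """Default MNI-like synthetic mask at 4 mm (≈30k mask voxels)."""
    return make_synthetic_mask()


@pytest.fixture(scope="session")
def samplers():
    return default_samplers()


@pytest.fixture(scope="session")
def tiny_grid():
    """Fully-masked 100-voxel grid for brute-force oracles."""
    return VoxelGrid(
        shape=(4, 5, 5),
        voxel_size=4.0,
        origin=np.zeros(3),
        mask=np.ones((4, 5, 5), dtype=bool),
    )
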