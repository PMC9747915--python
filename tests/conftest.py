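import numpy as np
import pytest

from radiomit.types import VoxelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng) -> VoxelImage:
    """12^3 random image with an off-centre ellipsoidal ROI."""
    shape = (12, 12, 12)
    intensities = 100.0 + 20.0 * rng.standard_normal(shape)
    grid = np.indices(shape, dtype=float)
    dist2 = ((grid[0] - 6) / 4.5) ** 2 + ((grid[1] - 5) / 3.5) ** 2 + (
        (grid[2] - 6) / 4.0
    ) ** 2
    mask = dist2 <= 1.0
    return VoxelImage(intensities, (1.0, 1.0, 2.0), mask)


@pytest.fixture
def line_image() -> VoxelImage:
    """1x1x4 ROI with levels [1, 1, 2, 2] after 2-bin discretization."""
    data = np.array([0.0, 0.0, 10.0, 10.0]).reshape(1, 1, 4)
    mask = np.ones((1, 1, 4), dtype=bool)
    return VoxelImage(data, (1.0, 1.0, 1.0), mask)


def random_level_volume(rng, shape=(5, 5, 5), n_levels=4, mask_p=0.8):
    """Random small discretized volume + mask for oracle cross-checks."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[0, 0, 0] = True
    return levels, mask
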