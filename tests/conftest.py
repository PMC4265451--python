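import numpy as np
import pytest

from petasp.pet_io import VoxelGrid
from petasp.phantoms import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def ball_r10():
    """Noiseless unblurred ball phantom, r = 10 mm at 1 mm spacing."""
    grid, mask, ref = make_phantom(
        PhantomSpec(shape="ball", radius_mm=10, psf_sigma_mm=0, grid_shape=(48, 48, 48))
    )
    return grid, mask, ref


@pytest.fixture(scope="session")
def ball_r20():
    """Noiseless unblurred ball phantom, r = 20 voxels at 1 mm spacing."""
    grid, mask, ref = make_phantom(
        PhantomSpec(shape="ball", radius_mm=20, psf_sigma_mm=0, grid_shape=(60, 60, 60))
    )
    return grid, mask, ref


@pytest.fixture(scope="session")
def cube_mask():
    """20^3-voxel cube mask on a 1 mm grid."""
    mask = np.zeros((30, 30, 30), dtype=bool)
    mask[5:25, 5:25, 5:25] = True
    grid = VoxelGrid(np.ones((30, 30, 30)), value_kind="suv")
    return grid, mask


@pytest.fixture(scope="session")
def two_level_grid():
    """Noiseless two-level image: lesion 11.0 on background 1.0."""
    vol = np.ones((32, 32, 32))
    vol[10:20, 10:20, 10:20] = 11.0
    return VoxelGrid(vol, value_kind="suv"), vol == 11.0
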