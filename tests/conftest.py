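import numpy as np
import pytest

from nodtex.segmentation import NoduleSegment
from nodtex.synthetic_data import PhantomSpec, generate_phantom
from nodtex.volume_io import CTVolume, NoduleMask


def make_segment(hu_grid, mask=None, spacing=(1.0, 1.0, 1.0), nodule_id="test"):
    """Build a NoduleSegment directly from a dense HU grid (no floor applied)."""
    hu_grid = np.asarray(hu_grid, dtype=float)
    if mask is None:
        mask = np.ones(hu_grid.shape, dtype=bool)
    coords = np.argwhere(mask)
    return NoduleSegment(
        coords=coords,
        hu=hu_grid[mask],
        spacing=spacing,
        shape=hu_grid.shape,
        nodule_id=nodule_id,
        hu_floor=-np.inf,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Clean d=10 mm sphere at 1 mm spacing: no blur, no calcification."""
    spec = PhantomSpec(
        shape="sphere", diameter_mm=10.0, nodule_hu_mean=50.0, nodule_hu_sd=0.0,
        parenchyma_hu_mean=-850.0, parenchyma_hu_sd=0.0, blur_mm=0.0, seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture
def random_volume_mask(rng):
    """Small random HU volume with a blob-ish random mask."""
    shape = (9, 10, 11)
    hu = rng.integers(-1000, 400, size=shape).astype(float)
    mask = np.zeros(shape, dtype=bool)
    mask[2:7, 3:8, 3:9] = rng.random((5, 5, 6)) < 0.7
    vol = CTVolume(voxels=hu, spacing=(1.0, 0.8, 0.8))
    return vol, NoduleMask(voxels=mask, spacing=vol.spacing, nodule_id="rand")
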