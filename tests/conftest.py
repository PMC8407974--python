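import numpy as np
import pytest

from tumorvol import SegmentationMask, rasterize_ellipsoid


@pytest.fixture(scope="session")
def sphere_r20():
    """Rasterized sphere, radius 20 mm, 1 mm isotropic voxels."""
    return rasterize_ellipsoid((20.0, 20.0, 20.0), case_id="sphere-r20")


@pytest.fixture(scope="session")
def cube_20mm():
    """Cube-shaped mask, 20 mm side, 1 mm voxels."""
    return SegmentationMask(np.ones((20, 20, 20), dtype=np.uint8), (1.0, 1.0, 1.0), "cube-20")


@pytest.fixture(scope="session")
def ellipsoid_252015():
    """Axis-aligned ellipsoid with half-axes (25, 20, 15) mm at 1 mm isotropic."""
    return rasterize_ellipsoid((15.0, 20.0, 25.0), case_id="ell-252015")


def single_voxel_mask(spacing=(4.0, 0.5, 0.5)):
    vox = np.zeros((3, 3, 3), dtype=np.uint8)
    vox[1, 1, 1] = 1
    return SegmentationMask(vox, spacing, "one-voxel")
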