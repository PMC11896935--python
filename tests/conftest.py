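import numpy as np
import pytest

from ventddi.grids import DefectMap, ImageGrid, LungMask


def iso_grid(shape, spacing=1.0):
    return ImageGrid(
        shape=shape,
        spacing=(spacing, spacing, spacing),
        slice_thickness=spacing,
        slice_gap=0.0,
    )


@pytest.fixture
def box_lung():
    """10x10x10 all-lung box on an isotropic unit grid (1000 voxels)."""
    grid = iso_grid((10, 10, 10))
    return LungMask(grid=grid, voxels=np.ones((10, 10, 10), dtype=np.uint8))


def make_defect(mask: LungMask, points) -> DefectMap:
    vox = np.zeros(mask.voxels.shape, dtype=np.uint8)
    for p in points:
        vox[tuple(p)] = 1
    return DefectMap(grid=mask.grid, voxels=vox)
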