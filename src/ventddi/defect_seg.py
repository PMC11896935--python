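"""Defect segmentation by relative-mean thresholding, and VDP.

A voxel is a ventilation defect when its signal is *strictly* below a fixed
fraction (default 60%) of the whole-lung mean intensity; the ventilation
defect percentage (VDP) is the defect voxel count as a percentage of the
lung voxel count.  Strict inequality means exact-boundary voxels survive as
ventilated — measure-zero in real data, but it keeps phantoms deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DefectMap, LungMask, VentilationImage, require_same_grid

DEFAULT_THRESHOLD_FRACTION = 0.60


@dataclass(frozen=True)
class VdpResult:
    vdp_percent: float
    threshold_value: float
    lung_voxel_count: int
    defect_voxel_count: int
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION


def whole_lung_mean(image: VentilationImage, mask: LungMask) -> float:
    """Arithmetic mean signal over lung-mask voxels."""
    require_same_grid(image.grid, mask.grid)
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("empty lung mask")
    return float(image.intensities[m].mean())


def segment_defects(
    image: VentilationImage,
    mask: LungMask,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> tuple[DefectMap, VdpResult]:
    """Threshold the image at ``threshold_fraction`` x whole-lung mean.

    Returns the binary defect map (subset of the lung mask) and the VDP
    summary.  The caller is expected to pass a bias-corrected image (or to
    opt out of correction deliberately).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    mean = whole_lung_mean(image, mask)
    threshold = threshold_fraction * mean
    m = mask.voxels.astype(bool)
    defect = m & (image.intensities < threshold)
    lung_count = int(m.sum())
    defect_count = int(defect.sum())
    result = VdpResult(
        vdp_percent=100.0 * defect_count / lung_count,
        threshold_value=threshold,
        lung_voxel_count=lung_count,
        defect_voxel_count=defect_count,
        threshold_fraction=threshold_fraction,
    )
    return DefectMap(grid=image.grid, voxels=defect.astype(np.uint8)), result


def vdp_from_maps(defect: DefectMap, mask: LungMask) -> float:
    """VDP directly from a defect map / lung mask pair (no image needed)."""
    defect.check_subset(mask)
    return 100.0 * defect.count / mask.count
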