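"""Core grid and volume types shared across the pipeline.

A multi-slice hyperpolarized-gas acquisition is a stack of thick 2D slices:
fine in-plane resolution (e.g. 3 x 3 mm) but coarse through-plane sampling
(e.g. 15 mm slices, optionally separated by a gap of up to 10 mm).  The grid
therefore carries, beyond the usual shape/spacing pair, the slice thickness
and slice gap needed to reason about which through-plane positions were
actually measured.

Conventions: voxel indices are 0-based, voxel centers sit at ``index *
spacing``, and the slice axis is the last array axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Orientation = Literal["axial", "coronal"]

_SPACING_TOL = 1e-6


@dataclass(frozen=True)
class ImageGrid:
    """Sampling geometry of a 3D multi-slice volume.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``; the last axis is the slice axis.
    spacing
        Millimetre spacing ``(dx, dy, dz)`` where ``dz`` is the distance
        between adjacent *slice centers* (thickness + gap).
    slice_thickness
        Excited slab thickness in mm.  Defaults to ``dz`` (contiguous
        slices, no gap).
    slice_gap
        Unsampled space between adjacent slabs in mm (>= 0).
    orientation
        Acquisition orientation tag.  Metadata only: it labels outputs for
        orientation comparisons but never alters any computation.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    slice_thickness: float = None  # type: ignore[assignment]
    slice_gap: float = 0.0
    orientation: Orientation = "axial"

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("grid shape and spacing must be length-3")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        if self.slice_gap < 0:
            raise ValueError("slice_gap must be >= 0")
        thickness = self.slice_thickness
        if thickness is None:
            thickness = spacing[2] - self.slice_gap
        thickness = float(thickness)
        if thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if abs(thickness + self.slice_gap - spacing[2]) > _SPACING_TOL:
            raise ValueError(
                "slice geometry inconsistent: thickness + gap = "
                f"{thickness + self.slice_gap:g} mm but center-to-center "
                f"spacing is {spacing[2]:g} mm"
            )
        if self.orientation not in ("axial", "coronal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "slice_thickness", thickness)
        object.__setattr__(self, "slice_gap", float(self.slice_gap))

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.spacing
        return abs(dx - dy) < _SPACING_TOL and abs(dx - dz) < _SPACING_TOL

    def with_orientation(self, orientation: Orientation) -> "ImageGrid":
        return replace(self, orientation=orientation)


def _check_array(grid: ImageGrid, arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D array, got ndim={arr.ndim}")
    if tuple(arr.shape) != grid.shape:
        raise ValueError(
            f"{what} shape {tuple(arr.shape)} does not match grid {grid.shape}"
        )
    return arr


@dataclass
class VentilationImage:
    """Scalar ventilation signal on a grid (arbitrary units, finite, >= 0)."""

    grid: ImageGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = _check_array(self.grid, self.intensities, "intensities")
        arr = np.asarray(arr, dtype=np.float64)
        bad = ~np.isfinite(arr)
        if bad.any():
            raise ValueError(
                f"intensities contain {int(bad.sum())} non-finite voxel(s)"
            )
        if (arr < 0).any():
            raise ValueError("intensities must be >= 0")
        self.intensities = arr


@dataclass
class BinaryVolume:
    """Binary 3D volume on a grid; base for masks and defect maps."""

    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        arr = _check_array(self.grid, self.voxels, type(self).__name__)
        self.voxels = np.asarray(arr != 0, dtype=np.uint8)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LungMask(BinaryVolume):
    """Lung parenchyma mask (large airways excluded upstream, at drawing time)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.count == 0:
            raise ValueError("lung mask has no foreground voxels")


@dataclass
class DefectMap(BinaryVolume):
    """Ventilation-defect voxels; must be a subset of the paired lung mask."""

    def check_subset(self, mask: LungMask) -> None:
        if tuple(self.voxels.shape) != tuple(mask.voxels.shape):
            raise ValueError("defect map and lung mask shapes differ")
        if np.any(self.voxels & ~mask.voxels):
            raise ValueError("defect voxels extend outside the lung mask")


@dataclass
class DDIMap:
    """Per-voxel defect distribution index on an isotropic grid.

    Nonzero only at true-slice defect voxels; 0 is background.
    """

    grid: ImageGrid
    values: np.ndarray
    z_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        arr = _check_array(self.grid, self.values, "DDI values")
        arr = np.asarray(arr, dtype=np.float32)
        if (arr < 0).any():
            raise ValueError("DDI values must be >= 0")
        self.values = arr


def same_grid(a: ImageGrid, b: ImageGrid) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=_SPACING_TOL)
        and abs(a.slice_thickness - b.slice_thickness) < _SPACING_TOL
        and abs(a.slice_gap - b.slice_gap) < _SPACING_TOL
    )


def require_same_grid(a: ImageGrid, b: ImageGrid) -> None:
    if not same_grid(a, b):
        raise ValueError(f"grids do not match: {a} vs {b}")
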