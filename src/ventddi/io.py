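"""NIfTI reading and writing with slice-geometry metadata.

A plain NIfTI header stores only the center-to-center slice spacing, not the
thickness/gap split, so ``slice_thickness`` and ``slice_gap`` are supplied by
the caller (CLI flag or config) and validated against the header's dz.
Orientation (axial vs coronal) is inferred from the header axes when
possible and can be overridden; it is metadata only.
"""

from __future__ import annotations

import os
from typing import Literal, Optional

import nibabel as nib
import numpy as np

from .grids import DDIMap, DefectMap, ImageGrid, LungMask, Orientation, VentilationImage

_SPACING_TOL = 1e-4


def _infer_orientation(affine: np.ndarray) -> Optional[Orientation]:
    """Map the slice (last) axis to an anatomical direction.

    Slices stacked along superior-inferior -> axial; along
    anterior-posterior -> coronal; anything else is undecidable.
    """
    try:
        codes = nib.aff2axcodes(affine)
    except Exception:
        return None
    last = codes[2]
    if last in ("S", "I"):
        return "axial"
    if last in ("A", "P"):
        return "coronal"
    return None


def _grid_from_header(
    img: nib.Nifti1Image,
    slice_thickness: Optional[float],
    slice_gap: float,
    orientation: Optional[Orientation],
) -> ImageGrid:
    shape = tuple(int(n) for n in img.shape[:3])
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    if orientation is None:
        orientation = _infer_orientation(img.affine) or "axial"
    if slice_thickness is not None:
        if abs(slice_thickness + slice_gap - spacing[2]) > _SPACING_TOL:
            raise ValueError(
                f"slice_thickness ({slice_thickness:g}) + slice_gap "
                f"({slice_gap:g}) must equal the header slice spacing "
                f"({spacing[2]:g} mm)"
            )
    else:
        slice_thickness = spacing[2] - slice_gap
    return ImageGrid(
        shape=shape,
        spacing=spacing,
        slice_thickness=slice_thickness,
        slice_gap=slice_gap,
        orientation=orientation,
    )


def read_volume(
    path: os.PathLike | str,
    kind: Literal["image", "mask"] = "image",
    *,
    slice_thickness: Optional[float] = None,
    slice_gap: float = 0.0,
    orientation: Optional[Orientation] = None,
) -> VentilationImage | LungMask:
    """Read a 3D NIfTI volume as a ventilation image or a binary lung mask.

    Masks are binarized (any nonzero voxel -> 1).  Rejects non-3D volumes,
    non-finite intensities, and empty masks.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_header(img, slice_thickness, slice_gap, orientation)
    if kind == "mask":
        return LungMask(grid=grid, voxels=np.asarray(data != 0, dtype=np.uint8))
    if kind != "image":
        raise ValueError(f"unknown kind {kind!r}")
    data = np.asarray(data, dtype=np.float64)
    bad = ~np.isfinite(data)
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} voxel(s) have non-finite intensity"
        )
    return VentilationImage(grid=grid, intensities=data)


def read_defect_map(
    path: os.PathLike | str,
    *,
    slice_thickness: Optional[float] = None,
    slice_gap: float = 0.0,
    orientation: Optional[Orientation] = None,
) -> DefectMap:
    mask = read_volume(
        path,
        kind="mask",
        slice_thickness=slice_thickness,
        slice_gap=slice_gap,
        orientation=orientation,
    )
    return DefectMap(grid=mask.grid, voxels=mask.voxels)


def _affine(grid: ImageGrid, z_origin: float = 0.0) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[2, 3] = z_origin
    return aff


def write_map(path: os.PathLike | str, volume: DDIMap | DefectMap | LungMask) -> None:
    """Write a DDI map (float32) or binary map (uint8) as NIfTI.

    Background voxels are 0; voxel spacing goes into the header zooms.
    """
    if isinstance(volume, DDIMap):
        data = np.asarray(volume.values, dtype=np.float32)
        z0 = volume.z_origin_mm
    elif isinstance(volume, (DefectMap, LungMask)):
        data = np.asarray(volume.voxels, dtype=np.uint8)
        z0 = 0.0
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    grid = volume.grid
    if tuple(data.shape) != grid.shape:
        raise ValueError(
            f"array shape {tuple(data.shape)} does not match grid {grid.shape}"
        )
    img = nib.Nifti1Image(data, _affine(grid, z0))
    img.header.set_zooms(grid.spacing)
    nib.save(img, os.fspath(path))


def write_image(path: os.PathLike | str, image: VentilationImage) -> None:
    img = nib.Nifti1Image(np.asarray(image.intensities, dtype=np.float32), _affine(image.grid))
    img.header.set_zooms(image.grid.spacing)
    nib.save(img, os.fspath(path))
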