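"""Synthetic lung phantoms with controlled defect clustering.

The phantoms emulate the validation setting for the DDI: binary lungs (two
ellipsoidal lobes, or a box) carrying a *fixed* defect burden — the defect
voxel count is hit exactly, so VDP is identical across clustering levels —
arranged at three clustering levels:

* ``high``   — the whole defect volume as one compact quasi-spherical blob;
* ``medium`` — 4-8 mid-size clusters;
* ``low``    — many (>= 40) scattered clusters of 1-5 voxels.

Defaults follow the simulated-lung study conditions: VDP 20%, lung sizes of
roughly 5040 / 12 200 / 20 045 voxels, isotropic 3 mm voxels.  Progression
transforms reproduce the two longitudinal scenarios (uniform worsening;
mixed improvement/worsening at exactly constant VDP), and uniform grid
refinement probes scale invariance of the DDI.

All randomness flows through one generator seeded from the PhantomSpec, so
identical specs reproduce identical volumes byte for byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .grids import DefectMap, ImageGrid, LungMask

Clustering = Literal["low", "medium", "high"]
LungShape = Literal["ellipsoid_pair", "box"]
ProgressionMode = Literal["worsen", "mixed_improve_worsen"]

# relative lobe semi-axes (x across, y front-back, z head-foot)
_LOBE_RATIOS = (1.0, 1.15, 1.6)


@dataclass(frozen=True)
class PhantomSpec:
    lung_shape: LungShape = "ellipsoid_pair"
    lung_voxel_target: int = 5040
    target_vdp: float = 20.0
    clustering: Clustering = "medium"
    n_clusters: Optional[int] = None
    cluster_radius_scale: float = 1.0
    seed: int = 0
    iso_spacing: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_vdp < 100.0:
            raise ValueError("target_vdp must be in (0, 100)")
        if self.lung_voxel_target < 100:
            raise ValueError("lung_voxel_target must be >= 100")
        if self.clustering not in ("low", "medium", "high"):
            raise ValueError(f"unknown clustering level {self.clustering!r}")
        if self.lung_shape not in ("ellipsoid_pair", "box"):
            raise ValueError(f"unknown lung shape {self.lung_shape!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _iso_grid(shape: tuple[int, int, int], spacing: float) -> ImageGrid:
    return ImageGrid(
        shape=shape,
        spacing=(spacing, spacing, spacing),
        slice_thickness=spacing,
        slice_gap=0.0,
    )


def make_lung(spec: PhantomSpec) -> LungMask:
    """Deterministic binary lung hitting the voxel target exactly.

    Ellipsoid pair: the normalized ellipsoid distance of every grid voxel to
    the nearer of two mirrored lobes is computed and the ``lung_voxel_target``
    smallest distances are foreground — an exact-count level set, so the
    realized count equals the target (the contract only demands 2%).
    """
    n = spec.lung_voxel_target
    if spec.lung_shape == "box":
        side = max(1, round(n ** (1.0 / 3.0)))
        ny = nz = side
        nx = max(1, round(n / (ny * nz)))
        shape = (nx + 2, ny + 2, nz + 2)
        vox = np.zeros(shape, dtype=np.uint8)
        vox[1 : nx + 1, 1 : ny + 1, 1 : nz + 1] = 1
        return LungMask(grid=_iso_grid(shape, spec.iso_spacing), voxels=vox)

    # per-lobe volume -> base semi-axis from the ellipsoid volume formula
    rx = (3.0 * (n / 2.0) / (4.0 * np.pi * _LOBE_RATIOS[1] * _LOBE_RATIOS[2])) ** (
        1.0 / 3.0
    )
    ry, rz = rx * _LOBE_RATIOS[1], rx * _LOBE_RATIOS[2]
    margin = 2.0
    # head-room factor 1.15 so the exact-count level set can spill slightly
    # past the nominal ellipsoid surface without clipping at the box edge
    hx, hy, hz = 1.15 * rx, 1.15 * ry, 1.15 * rz
    sep = 0.35 * rx  # half-gap between the two lobes (mediastinum)
    shape = (
        int(np.ceil(2 * (2 * hx + sep + margin))),
        int(np.ceil(2 * (hy + margin))),
        int(np.ceil(2 * (hz + margin))),
    )
    cx, cy, cz = ((s - 1) / 2.0 for s in shape)
    X, Y, Z = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    d2 = np.minimum(
        ((X - (cx - (rx + sep))) / rx) ** 2,
        ((X - (cx + (rx + sep))) / rx) ** 2,
    ) + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n]
    vox = np.zeros(d2.size, dtype=np.uint8)
    vox[order] = 1
    return LungMask(grid=_iso_grid(shape, spec.iso_spacing), voxels=vox.reshape(shape))


def _defect_target(spec: PhantomSpec, lung_count: int) -> int:
    return int(round(spec.target_vdp / 100.0 * lung_count))


_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


def _block_halo(blocked: np.ndarray, points: np.ndarray) -> None:
    """Mark the face-neighbors of ``points`` as off-limits for new clusters."""
    shape = np.array(blocked.shape)
    for off in _FACE_OFFSETS:
        p = points + off
        ok = np.all((p >= 0) & (p < shape), axis=1)
        p = p[ok]
        blocked[p[:, 0], p[:, 1], p[:, 2]] = True


def _cluster_sizes(spec: PhantomSpec, n_def: int, rng: np.random.Generator) -> list[int]:
    if spec.clustering == "high":
        return [n_def]
    if spec.clustering == "medium":
        k = spec.n_clusters or int(rng.integers(4, 9))
        base = n_def // k
        sizes = [base] * k
        for i in range(n_def - base * k):
            sizes[i] += 1
        # +-20% jitter, renormalized back to the exact total
        jitter = rng.uniform(0.8, 1.2, size=k)
        sizes = np.maximum(1, np.round(np.array(sizes) * jitter)).astype(int)
        while sizes.sum() > n_def:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < n_def:
            sizes[np.argmin(sizes)] += 1
        return [int(s) for s in sizes]
    # low: scattered clusters of 1-5 voxels; cap sizes so there are >= 40
    # clusters whenever the defect budget allows it
    max_size = 5
    if n_def >= 40:
        max_size = min(5, max(1, n_def // 40))
    sizes: list[int] = []
    remaining = n_def
    while remaining > 0:
        s = int(rng.integers(1, max_size + 1))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def place_defects(mask: LungMask, spec: PhantomSpec) -> DefectMap:
    """Seeded defect placement hitting the target VDP count exactly.

    Clusters grow as nearest-voxel balls around seeded centers inside the
    lung.  Distinct clusters are kept non-face-adjacent via a one-voxel
    halo, so they remain separate face-connected components (the package's
    component convention); the total defect count equals
    ``round(target_vdp/100 x lung_count)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    lung = mask.voxels.astype(bool)
    lung_count = int(lung.sum())
    n_def = _defect_target(spec, lung_count)
    if n_def > lung_count:
        raise ValueError("requested defect volume exceeds the lung volume")

    defect = np.zeros(lung.shape, dtype=bool)
    blocked = np.zeros(lung.shape, dtype=bool)  # halo of finished clusters
    sizes = _cluster_sizes(spec, n_def, rng)

    deep_pool: np.ndarray | None = None
    if spec.clustering == "high":
        # seed deep in the lung so the blob stays compact: pick among the
        # most interior voxels by distance transform
        dt = ndimage.distance_transform_edt(lung)
        depths = dt[lung]
        coords_lung = np.argwhere(lung)
        deep_pool = coords_lung[depths >= 0.8 * depths.max()]

    for size in sizes:
        pool = np.argwhere(lung & ~defect & ~blocked)
        if len(pool) == 0:
            break
        if deep_pool is not None:
            center = deep_pool[rng.integers(len(deep_pool))]
        else:
            center = pool[rng.integers(len(pool))]
        d2 = np.sum((pool - center) ** 2, axis=1)
        take = pool[np.argsort(d2, kind="stable")[: min(size, len(pool))]]
        defect[take[:, 0], take[:, 1], take[:, 2]] = True
        _block_halo(blocked, take)

    # pad voxel-by-voxel if halo exclusion ran the pool dry mid-cluster:
    # first as extra separated singles, then (if truly jammed) anywhere
    shortfall = n_def - int(defect.sum())
    while shortfall > 0:
        pool = np.argwhere(lung & ~defect & ~blocked)
        if len(pool) == 0:
            pool = np.argwhere(lung & ~defect)
        p = pool[rng.integers(len(pool))]
        defect[p[0], p[1], p[2]] = True
        _block_halo(blocked, p[None, :])
        shortfall -= 1

    out = DefectMap(grid=mask.grid, voxels=defect.astype(np.uint8))
    assert out.count == n_def
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[LungMask, DefectMap]:
    mask = make_lung(spec)
    return mask, place_defects(mask, spec)


# ---------------------------------------------------------------------------
# progression


def _dilate_within(defect: np.ndarray, lung: np.ndarray, n_add: int, rng) -> np.ndarray:
    """Add up to ``n_add`` voxels by repeated dilation clipped to the lung."""
    out = defect.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    while n_add > 0:
        ring = ndimage.binary_dilation(out, struct) & lung & ~out
        ring_idx = np.argwhere(ring)
        if len(ring_idx) == 0:
            break
        if len(ring_idx) <= n_add:
            out[ring] = True
            n_add -= len(ring_idx)
        else:
            pick = rng.choice(len(ring_idx), size=n_add, replace=False)
            pts = ring_idx[pick]
            out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            n_add = 0
    return out


def progress(
    defect: DefectMap,
    mask: LungMask,
    mode: ProgressionMode,
    spec: PhantomSpec,
    *,
    grow_fraction: float = 0.4,
) -> DefectMap:
    """Longitudinal transform of a defect map.

    ``worsen`` dilates existing clusters (and seeds a few new ones), so VDP
    strictly increases.  ``mixed_improve_worsen`` deletes some clusters and
    regrows the survivors under an exact-count constraint, so VDP is
    unchanged while the arrangement consolidates into fewer, larger
    clusters (which raises the DDI).
    """
    rng = np.random.default_rng(spec.seed + 104729)  # decouple from placement
    lung = mask.voxels.astype(bool)
    d = defect.voxels.astype(bool)
    n0 = int(d.sum())
    if n0 == 0:
        raise ValueError("cannot progress an empty defect map")

    if mode == "worsen":
        n_add = max(1, int(round(grow_fraction * n0)))
        if n0 + n_add > lung.sum():
            raise ValueError("worsening infeasible: lung already saturated")
        out = _dilate_within(d, lung, n_add, rng)
        if out.sum() <= n0:
            raise ValueError("worsening infeasible: defects cannot grow")
        return DefectMap(grid=defect.grid, voxels=out.astype(np.uint8))

    if mode != "mixed_improve_worsen":
        raise ValueError(f"unknown progression mode {mode!r}")

    labels, n_comp = ndimage.label(d)  # face connectivity
    if n_comp == 1:
        # single blob: shrink it to a core and scatter the freed volume as
        # new small defects elsewhere
        keep = max(1, int(round((1.0 - grow_fraction) * n0)))
        core_coords = np.argwhere(d)
        centroid = core_coords.mean(axis=0)
        d2 = np.sum((core_coords - centroid) ** 2, axis=1)
        kept = core_coords[np.argsort(d2, kind="stable")[:keep]]
        out = np.zeros_like(d)
        out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
        budget = n0 - keep
        free = np.argwhere(lung & ~out)
        # new scattered 1-3 voxel defects away from the core
        while budget > 0 and len(free):
            c = free[rng.integers(len(free))]
            size = min(budget, int(rng.integers(1, 4)))
            d2f = np.sum((free - c) ** 2, axis=1)
            pts = free[np.argsort(d2f, kind="stable")[:size]]
            out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            free = np.argwhere(lung & ~out)
            budget = n0 - int(out.sum())
    else:
        comp_ids = rng.permutation(np.arange(1, n_comp + 1))
        removed = 0
        target_removed = int(round(grow_fraction * n0))
        out = d.copy()
        for cid in comp_ids:
            if removed >= target_removed or (n_comp - 1) <= 0:
                break
            comp = labels == cid
            csize = int(comp.sum())
            if removed + csize > n0 - 1:  # never delete everything
                continue
            out[comp] = False
            removed += csize
            n_comp -= 1
        out = _dilate_within(out, lung, n0 - int(out.sum()), rng)
        if int(out.sum()) != n0:
            raise ValueError("mixed progression infeasible: lung too small")
    assert int(out.sum()) == n0
    return DefectMap(grid=defect.grid, voxels=out.astype(np.uint8))


# ---------------------------------------------------------------------------
# scaling


def rescale(
    defect: DefectMap, mask: LungMask, factor: int
) -> tuple[DefectMap, LungMask]:
    """Uniform nearest-neighbor refinement by an integer factor per axis.

    Voxel counts scale by factor^3 and the defect fraction (hence VDP) is
    preserved exactly; voxel spacing shrinks by the factor so the physical
    lung is unchanged.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)

    def refine(arr: np.ndarray) -> np.ndarray:
        return (
            arr.repeat(factor, axis=0).repeat(factor, axis=1).repeat(factor, axis=2)
        )

    g = mask.grid
    s = g.spacing[0] / factor
    new_grid = ImageGrid(
        shape=tuple(n * factor for n in g.shape),
        spacing=(g.spacing[0] / factor, g.spacing[1] / factor, g.spacing[2] / factor),
        slice_thickness=g.slice_thickness / factor,
        slice_gap=g.slice_gap / factor,
        orientation=g.orientation,
    )
    new_mask = LungMask(grid=new_grid, voxels=refine(mask.voxels))
    new_defect = DefectMap(grid=new_grid, voxels=refine(defect.voxels))
    return new_defect, new_mask
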