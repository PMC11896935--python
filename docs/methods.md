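# Methods

## The measurement problem

Hyperpolarized-gas ventilation MRI maps the distribution of an inhaled
tracer gas during a breath-hold. Regions of low signal mark obstructed or
poorly ventilated lung. The standard summary, the ventilation defect
percentage (VDP), counts defect voxels as a fraction of the lung but is
blind to their spatial arrangement: focal segment-level obstruction and
diffuse small-airway disease can produce identical VDP. The defect
distribution index (DDI) quantifies that arrangement — low values for
scattered defects, high values for consolidated ones — so that the two
phenotypes separate.

## Pipeline

1. **Bias correction.** Ventilation signal is modulated by the coil
   sensitivity (B1) field. The image is divided by a smooth multiplicative
   field estimated *inside the lung mask only* and renormalized so the
   in-mask mean is exactly preserved; the 60%-of-mean threshold is then
   comparable before and after. Two estimators are available: N4 (via
   SimpleITK, default in the CLI) and a self-contained log-domain
   polynomial least-squares fit (order 2 by default, orders 1–4 allowed).
   The polynomial fit uses only voxels above 60% of the in-mask median so
   that genuine defects are not absorbed into the estimated field; N4's
   spline regularization serves the same purpose. N4 parameters not set
   explicitly (shrink factor, spline spacing) are SimpleITK defaults and
   are recorded in the output provenance block.

2. **Defect segmentation.** A lung voxel is a defect when its corrected
   signal is *strictly* below `threshold_fraction` (default 0.60) times
   the whole-lung mean, the mean being computed on the corrected image
   (order: correct → mean → threshold). Strict inequality makes
   exact-boundary voxels ventilated — measure-zero in vivo, but it keeps
   phantoms deterministic. VDP = 100 × defects / lung voxels, on the
   acquisition grid. The segmentation is invariant under global intensity
   scaling, and lowering the threshold fraction can only shrink the defect
   set.

3. **Isotropic interpolation.** Multi-slice acquisitions are anisotropic
   (e.g. 3 × 3 mm in-plane, 15 mm slices, gaps up to 10 mm). The defect
   map and lung mask are resampled by nearest neighbor to cubic voxels at
   the in-plane spacing: output planes tile the physical slab extent (from
   half a slice thickness above the first slice center to half below the
   last) and each copies the slice whose center is nearest. With
   contiguous 15 mm slices and 3 mm in-plane voxels every slice is
   replicated exactly five times; already-isotropic input passes through
   unchanged. A `true_slice_mask` marks voxels whose center lies within
   half a slice thickness of an acquired slice center: only these can host
   sphere centers, while gap-filling planes still contribute to sphere
   counts. As a guard for degenerate geometries (thickness smaller than
   the in-plane spacing), the plane nearest each slice center is always
   marked true, so every acquired defect voxel retains a true-slice image.
   In-plane downsampling (slice spacing finer than in-plane spacing) is
   rejected rather than silently aggregated.

4. **Sphere expansion.** For each true-slice defect voxel a sphere is
   grown until the defect fraction inside falls below
   `majority_fraction` (default 0.5). Geometry is discrete: a sphere of
   radius r is the set of voxel centers within Euclidean distance r of the
   center voxel, and the radius steps through *every distance the lattice
   realizes* — squared radii r² = 0, 1, 2, 3, 4, 5, 6, 8, … (7, 15, … are
   skipped; no integer triple has those squared norms). This is the finest
   schedule the discretization supports. Whole-voxel radius steps were
   rejected because their stopping radius systematically rounds down by up
   to half a voxel, biasing sphere volumes by ~15% at typical radii and
   breaking the scale invariance of the index across image resolutions;
   with the lattice schedule the same defect pattern rendered at 8× the
   voxel count changes the mean DDI by only a few percent.

   Two conventions are configurable:
   - `radius_convention` — `last_majority` (default) reports the largest
     sphere still majority-defect, so an isolated defect voxel scores a
     single-voxel sphere; `first_minority` reports the first sphere whose
     fraction dropped below the threshold.
   - `denominator` — `all_voxels` (default) counts every in-bounds voxel
     inside the sphere, lung or not; `lung_only` restricts the denominator
     to lung voxels. Out-of-image voxels never count on either side.

   Growth is capped at the image diagonal (in voxel units); a fully
   defective volume hits the cap and sets a per-voxel warning flag instead
   of failing. Ties (fraction exactly at the threshold) count as majority,
   so growth continues.

   Internally the whole-map computation batches all centers per shell with
   FFT convolutions (counts rounded back to exact integers); the public
   single-center routine accumulates lattice shells with integer
   arithmetic. The two are exact-equal by construction and are checked
   against a brute-force distance-thresholding oracle in the test suite.

5. **Score and index.** The final sphere yields
   `score = sphere voxels / isotropic lung voxels` and `DDI = 100 × score`.
   Both counts scale identically under uniform grid refinement, which is
   what makes the index comparable across lung sizes and resolutions. The
   whole-lung summary takes the mean and max over true-slice defect voxels
   (zero, by definition, when there are none, and flagged as such), VDP
   from the acquisition grid, and DDI/VDP — reported as *missing*, not 0,
   when VDP = 0. For one compact defect occupying fraction f of the lung,
   the core sphere grows to ≈ 2f of the lung before losing its majority,
   so the peak DDI approaches 2 × VDP; surface voxels stop almost
   immediately, which is why the whole-lung mean sits well below the peak.

## Synthetic phantoms

The phantom generator provides the controlled setting in which the index's
properties are demonstrated and tested. Defaults are the simulated-lung
study conditions: VDP fixed at 20%, lung sizes around 5040 / 12 200 /
20 045 voxels, isotropic 3 mm voxels.

- **Lung shape.** Two mirrored ellipsoidal lobes (semi-axis ratios
  1 : 1.15 : 1.6, a mediastinal gap of 0.35 lobe radii) or a box. The
  foreground is the exact-count level set of the normalized ellipsoid
  distance field, so the realized lung voxel count equals the target
  exactly and is deterministic.
- **Defect placement.** The defect budget is `round(VDP/100 × lung)`
  voxels, hit exactly at every clustering level; this is what makes the
  clustering comparison clean. `high` grows one quasi-spherical blob
  seeded among the most interior lung voxels (by distance transform);
  `medium` grows 4–8 clusters of near-equal size (±20% jitter); `low`
  scatters ≥ 40 clusters of 1–5 voxels. Distinct clusters are kept
  non-face-adjacent by a one-voxel halo; face connectivity (6-neighborhood)
  is the component convention throughout. Full 26-separation is
  geometrically infeasible at a 20% fill with clusters this small, and
  face adjacency is the notion under which the scattered pattern stays
  scattered. All placement flows through one seeded generator; identical
  specs reproduce identical volumes byte for byte.
- **Progression.** `worsen` dilates clusters inside the lung (plus
  dilation-ring fill), strictly increasing VDP. `mixed_improve_worsen`
  deletes some clusters and regrows the survivors under an exact-count
  constraint: VDP is unchanged while the arrangement consolidates, which
  raises the mean DDI — the longitudinal scenario in which VDP alone would
  report "no change".
- **Refinement.** `rescale` performs nearest-neighbor refinement by an
  integer factor per axis: voxel counts ×factor³, defect fraction exactly
  preserved, physical geometry unchanged. Used to probe scale invariance.

What the phantoms do *not* emulate: MRI signal and noise physics, partial
volume, airway trees, anatomically realistic lung outlines, or the
defect-geometry details behind any published figure. Passing phantom tests
demonstrates the metric's mathematical behavior (ordering, scale
invariance, progression contracts) — not segmentation performance on real
scans, which depends on mask quality and bias correction upstream.

## Cohort statistics

The analysis layer operates on a subject-level table (group, category,
orientation, mean DDI, VDP, DDI/VDP, optional percent-predicted FEV₁, FVC,
FEV₁/FVC):

- Per-group Pearson correlations for DDI–VDP and metric–PFT pairs,
  pairwise-complete over missing PFTs; a pair with fewer than three
  complete observations is reported missing rather than as a number.
- Kruskal–Wallis omnibus tests per metric across disease groups or
  categories. Pairwise comparisons (rank-sum by default, Dunn's z-test as
  a switch) report *unadjusted* p-values flagged against a
  Bonferroni-adjusted threshold — 0.05/9 at group level, 0.05/4 at
  category level — mirroring the report-unadjusted /
  compare-to-adjusted-threshold convention, and the columns are labelled
  accordingly.
- Axial-vs-coronal comparison within a group by two-tailed t-test at
  P < 0.05; a group missing one orientation yields missing results.

Orientation is metadata throughout: it tags outputs for these comparisons
but never changes any computation.

## Problem sizes and numerical choices

- Phantom tests run at the 5040-voxel lung size (grids around 41 × 23 × 30)
  with refinement to ≈ 40 000 voxels for the scale-invariance check; the
  clustering-ordering property is asserted over 100 seeded phantom triples.
- Scale invariance is asserted for the medium and high patterns, where
  spheres span many voxels. The low-clustering pattern sits at the
  resolution floor of the metric — single-voxel defects produce
  single-voxel spheres, so refinement changes its mean DDI by a large
  relative factor on a value of ~0.04 (absolute change ~0.01); a relative
  bound is not meaningful there.
- FFT-convolution counts are rounded to the nearest integer; double
  precision makes this exact for any volume these analyses meet.
- Majority comparisons use `count ≥ fraction × total − 1e-9`; with the
  default fraction 0.5 the product is exact in binary and ties are
  genuine ties (counted as majority).
- DDI maps are written as float32 NIfTI with 0 background; defect and lung
  maps as uint8. The slice-axis origin of the isotropic grid is carried in
  the NIfTI affine.

## Limitations

- The cluster score and DDI mapping implemented here are the documented
  sphere-volume-fraction form; DDI values are comparable within this
  package but not guaranteed numerically identical to other DDI
  implementations, whose score normalization may differ in detail.
- Binary defect maps discard signal texture within defects; the index
  sees geometry only.
- Nearest-neighbor slice interpolation cannot recover structure inside
  slice gaps; gap planes inherit the nearest slice's pattern and true 3D
  isotropic acquisitions would be preferable.
- The mean DDI of diffuse patterns is resolution-limited (see above):
  comparisons of very low DDI values across differing resolutions should
  use matched grids.
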