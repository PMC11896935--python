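import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventddi.ddi3d import (
    DdiConfig,
    cluster_score,
    compute_ddi_map,
    ddi_value,
    default_r_max,
    expand_sphere,
    interpolate_isotropic,
    sphere_offsets,
)
from ventddi.grids import DefectMap, ImageGrid, LungMask

from conftest import iso_grid, make_defect


def enumerate_ball(radius):
    """Brute-force lattice enumeration: all |v|^2 <= r^2 in a cube scan."""
    pts = []
    for x in range(-radius, radius + 1):
        for y in range(-radius, radius + 1):
            for z in range(-radius, radius + 1):
                if x * x + y * y + z * z <= radius * radius:
                    pts.append((x, y, z))
    return set(pts)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_counts_against_enumeration(self, radius, count):
        offsets = sphere_offsets(radius)
        assert len(offsets) == count
        assert {tuple(v) for v in offsets} == enumerate_ball(radius)

    @settings(derandomize=True, max_examples=7, deadline=None)
    @given(radius=st.integers(0, 6))
    def test_matches_enumeration_for_any_radius(self, radius):
        assert {tuple(v) for v in sphere_offsets(radius)} == enumerate_ball(radius)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


def iso_volume(defect: DefectMap, mask: LungMask):
    return interpolate_isotropic(defect, mask)


class TestInterpolation:
    def test_contiguous_thick_slices_replicated_5x(self):
        """3 x 3 x 15 mm grid, zero gap: each slice replicated 5x at 3 mm."""
        grid = ImageGrid(shape=(4, 4, 3), spacing=(3, 3, 15))
        lung = LungMask(grid=grid, voxels=np.ones((4, 4, 3), dtype=np.uint8))
        vox = np.zeros((4, 4, 3), dtype=np.uint8)
        vox[1, 1, 1] = 1  # defect only in the middle slice
        iso = interpolate_isotropic(DefectMap(grid=grid, voxels=vox), lung)
        assert iso.iso_spacing == 3.0
        assert iso.voxels.shape == (4, 4, 15)
        # middle slice occupies exactly output planes 5..9
        z_profile = iso.voxels[1, 1, :]
        assert list(np.flatnonzero(z_profile)) == [5, 6, 7, 8, 9]
        # zero gap: every plane lies within thickness/2 of a slice center
        assert iso.true_slice_mask.all()
        assert set(np.unique(iso.voxels)) <= {0, 1}

    def test_isotropic_zero_gap_is_identity(self, box_lung):
        defect = make_defect(box_lung, [(2, 3, 4), (5, 5, 5)])
        iso = interpolate_isotropic(defect, box_lung)
        assert np.array_equal(iso.voxels, defect.voxels)
        assert np.array_equal(iso.lung, box_lung.voxels)
        assert iso.true_slice_mask.all()

    def test_gap_planes_inherit_nearest_slice_but_are_not_true(self):
        """Thickness 15, gap 10 (centers every 25 mm), 3 slices, 3 mm planes.

        Plane centers at z = 3j - 6 mm; slice centers at 0, 25, 50 mm.
        Hand enumeration: planes within 7.5 mm of a center are true.
        """
        grid = ImageGrid(
            shape=(2, 2, 3), spacing=(3, 3, 25), slice_thickness=15, slice_gap=10
        )
        lung = LungMask(grid=grid, voxels=np.ones((2, 2, 3), dtype=np.uint8))
        vox = np.zeros((2, 2, 3), dtype=np.uint8)
        vox[:, :, 1] = 1  # middle slice fully defective
        iso = interpolate_isotropic(DefectMap(grid=grid, voxels=vox), lung)
        n_out = iso.voxels.shape[2]
        assert n_out == round(((3 - 1) * 25 + 15) / 3)  # 22 planes
        z = -7.5 + (np.arange(n_out) + 0.5) * 3.0
        nearest = np.clip(np.round(z / 25.0).astype(int), 0, 2)
        expected_defect = (nearest == 1).astype(np.uint8)
        assert np.array_equal(iso.voxels[0, 0, :], expected_defect)
        expected_true = np.abs(z - nearest * 25.0) <= 7.5 + 1e-9
        assert np.array_equal(iso.true_slice_mask[0, 0, :].astype(bool), expected_true)
        # gap planes exist and carry values without being true slices
        assert (~expected_true).sum() > 0

    def test_every_slice_retains_a_true_plane(self):
        # thin slices with a wide gap: nearest plane per slice is kept true
        grid = ImageGrid(
            shape=(2, 2, 4), spacing=(3, 3, 12), slice_thickness=2, slice_gap=10
        )
        lung = LungMask(grid=grid, voxels=np.ones((2, 2, 4), dtype=np.uint8))
        vox = np.ones((2, 2, 4), dtype=np.uint8)
        iso = interpolate_isotropic(DefectMap(grid=grid, voxels=vox), lung)
        z = iso.z_origin_mm + np.arange(iso.voxels.shape[2]) * iso.iso_spacing
        for k in range(4):
            j = int(np.argmin(np.abs(z - k * 12.0)))
            assert iso.true_slice_mask[0, 0, j]

    def test_anisotropic_in_plane_rejected(self):
        grid = ImageGrid(shape=(4, 4, 3), spacing=(3, 4, 15))
        lung = LungMask(grid=grid, voxels=np.ones((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="in-plane"):
            interpolate_isotropic(
                DefectMap(grid=grid, voxels=np.zeros((4, 4, 3))), lung
            )

    def test_downsampling_rejected(self):
        grid = ImageGrid(shape=(4, 4, 6), spacing=(3, 3, 1), slice_thickness=1)
        lung = LungMask(grid=grid, voxels=np.ones((4, 4, 6), dtype=np.uint8))
        with pytest.raises(ValueError, match="downsampling"):
            interpolate_isotropic(
                DefectMap(grid=grid, voxels=np.zeros((4, 4, 6))), lung
            )


class TestExpandSphere:
    def test_isolated_defect_voxel_stops_at_radius_zero(self, box_lung):
        defect = make_defect(box_lung, [(5, 5, 5)])
        res = expand_sphere(iso_volume(defect, box_lung), (5, 5, 5))
        # r=0: fraction 1; r=1: 1/7 < 0.5 -> final radius 0
        assert res.final_radius == 0
        assert res.sphere_voxel_count == 1
        assert res.defect_in_sphere_count == 1
        assert not res.capped

    def test_solid_cube_expands_to_radius_two(self):
        """3x3x3 defect cube deep in a large ventilated lung.

        The sphere stays majority-defect through r = 2 (27 of 33 voxels
        defect, the whole cube inside) and first drops below 50% at the
        next lattice shell (r^2 = 5: 27/57) -> final radius 2 with 33
        sphere voxels, 27 of them defect.
        """
        grid = iso_grid((21, 21, 21))
        lung = LungMask(grid=grid, voxels=np.ones((21, 21, 21), dtype=np.uint8))
        vox = np.zeros((21, 21, 21), dtype=np.uint8)
        vox[9:12, 9:12, 9:12] = 1
        res = expand_sphere(iso_volume(DefectMap(grid=grid, voxels=vox), lung), (10, 10, 10))
        assert res.final_radius == 2
        assert res.sphere_voxel_count == 33
        assert res.defect_in_sphere_count == 27

    def test_first_minority_convention_reports_next_shell(self):
        # the first minority sphere is the next lattice shell, r^2 = 5
        grid = iso_grid((21, 21, 21))
        lung = LungMask(grid=grid, voxels=np.ones((21, 21, 21), dtype=np.uint8))
        vox = np.zeros((21, 21, 21), dtype=np.uint8)
        vox[9:12, 9:12, 9:12] = 1
        res = expand_sphere(
            iso_volume(DefectMap(grid=grid, voxels=vox), lung),
            (10, 10, 10),
            DdiConfig(radius_convention="first_minority"),
        )
        assert res.final_radius == pytest.approx(np.sqrt(5))
        assert res.sphere_voxel_count == 57
        assert res.defect_in_sphere_count == 27

    def test_fully_defective_volume_hits_cap(self, box_lung):
        defect = DefectMap(
            grid=box_lung.grid, voxels=np.ones((10, 10, 10), dtype=np.uint8)
        )
        res = expand_sphere(iso_volume(defect, box_lung), (5, 5, 5))
        assert res.capped
        assert res.final_radius == default_r_max((10, 10, 10))
        assert res.sphere_voxel_count == 1000  # whole image eventually inside

    def test_non_defect_center_rejected(self, box_lung):
        defect = make_defect(box_lung, [(5, 5, 5)])
        with pytest.raises(ValueError, match="not a defect"):
            expand_sphere(iso_volume(defect, box_lung), (0, 0, 0))


class TestScoreAndValue:
    def test_isolated_voxel_score_and_ddi(self):
        from ventddi.ddi3d import SphereExpansionResult

        res = SphereExpansionResult((0, 0, 0), 0, 1, 1)
        score = cluster_score(res, 1000)
        assert score == pytest.approx(0.001)
        assert ddi_value(score) == pytest.approx(0.1)

    def test_full_lung_sphere_scores_one(self):
        from ventddi.ddi3d import SphereExpansionResult

        res = SphereExpansionResult((0, 0, 0), 9, 1000, 800)
        assert cluster_score(res, 1000) == 1.0
        assert ddi_value(1.0) == 100.0

    def test_score_invariant_under_uniform_refinement(self):
        from ventddi.ddi3d import SphereExpansionResult

        res = SphereExpansionResult((0, 0, 0), 2, 33, 27)
        res8 = SphereExpansionResult((0, 0, 0), 4, 33 * 8, 27 * 8)
        assert cluster_score(res8, 8000) == pytest.approx(cluster_score(res, 1000))

    def test_ddi_monotone_in_score(self):
        scores = np.linspace(0, 1, 11)
        vals = [ddi_value(s) for s in scores]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert ddi_value(0.0) == 0.0


class TestComputeDdiMap:
    def test_empty_defect_map_all_zero(self, box_lung):
        defect = DefectMap(
            grid=box_lung.grid, voxels=np.zeros((10, 10, 10), dtype=np.uint8)
        )
        ddi_map, summary = compute_ddi_map(defect, box_lung)
        assert summary.mean_ddi == 0.0
        assert summary.max_ddi == 0.0
        assert summary.vdp_percent == 0.0
        assert summary.ddi_over_vdp is None  # undefined at VDP 0, not 0
        assert not ddi_map.values.any()

    def test_isolated_voxel_in_1000_voxel_lung(self, box_lung):
        defect = make_defect(box_lung, [(5, 5, 5)])
        ddi_map, summary = compute_ddi_map(defect, box_lung)
        assert summary.mean_ddi == pytest.approx(0.1)
        assert summary.max_ddi == pytest.approx(0.1)
        assert ddi_map.values[5, 5, 5] == pytest.approx(0.1)
        assert np.count_nonzero(ddi_map.values) == 1
        assert summary.ddi_over_vdp == pytest.approx(0.1 / summary.vdp_percent)

    def test_values_only_at_true_slice_defect_voxels(self):
        grid = ImageGrid(shape=(6, 6, 3), spacing=(3, 3, 25), slice_thickness=15, slice_gap=10)
        lung = LungMask(grid=grid, voxels=np.ones((6, 6, 3), dtype=np.uint8))
        vox = np.zeros((6, 6, 3), dtype=np.uint8)
        vox[2:4, 2:4, 1] = 1
        ddi_map, summary = compute_ddi_map(DefectMap(grid=grid, voxels=vox), lung)
        iso = interpolate_isotropic(DefectMap(grid=grid, voxels=vox), lung)
        nonzero = ddi_map.values > 0
        allowed = (iso.voxels & iso.true_slice_mask).astype(bool)
        assert not np.any(nonzero & ~allowed)
        assert summary.center_count == int(allowed.sum())

    def test_mean_never_exceeds_max(self, box_lung):
        rng = np.random.default_rng(3)
        vox = (rng.random((10, 10, 10)) < 0.15).astype(np.uint8)
        defect = DefectMap(grid=box_lung.grid, voxels=vox)
        _, summary = compute_ddi_map(defect, box_lung)
        assert summary.mean_ddi <= summary.max_ddi

    def test_deterministic_bit_identical(self, box_lung):
        rng = np.random.default_rng(7)
        vox = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
        defect = DefectMap(grid=box_lung.grid, voxels=vox)
        m1, s1 = compute_ddi_map(defect, box_lung)
        m2, s2 = compute_ddi_map(defect, box_lung)
        assert np.array_equal(m1.values, m2.values)
        assert s1.mean_ddi == s2.mean_ddi and s1.max_ddi == s2.max_ddi

    def test_batch_matches_single_center_expansion(self, box_lung):
        """The FFT-batched expansion and the exact shell accumulation agree."""
        rng = np.random.default_rng(11)
        vox = (rng.random((10, 10, 10)) < 0.3).astype(np.uint8)
        defect = DefectMap(grid=box_lung.grid, voxels=vox)
        iso = interpolate_isotropic(defect, box_lung)
        ddi_map, summary = compute_ddi_map(defect, box_lung)
        lung_iso = iso.lung_voxel_count
        for center in np.argwhere(vox):
            res = expand_sphere(iso, tuple(center))
            expected = ddi_value(cluster_score(res, lung_iso))
            assert ddi_map.values[tuple(center)] == pytest.approx(expected, rel=1e-6)
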