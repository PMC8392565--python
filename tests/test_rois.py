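"""Sphere construction, hemisphere partition, mirroring, lateralized sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemiconn as hc
from hemiconn import rois


def brute_force_sphere_count(grid, center, radius):
    count = 0
    for i, x in enumerate(grid.axis_coords(0)):
        for j, y in enumerate(grid.axis_coords(1)):
            for k, z in enumerate(grid.axis_coords(2)):
                if (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2:
                    count += 1
    return count


class TestSphere:
    def test_tiny_radius_selects_single_nearest_voxel(self, small_grid):
        defn = hc.ROIDefinition("dot", "ToM", "midline", (0.4, 0.3, -0.2), radius=0.9)
        mask = hc.build_sphere_roi(defn, small_grid)
        assert mask.n_voxels == 1
        idx = np.argwhere(mask.data)[0]
        assert tuple(idx) == (5, 4, 3)  # nearest center is the grid origin voxel

    def test_count_matches_exhaustive_scan(self, small_grid):
        defn = hc.ROIDefinition("s", "PAIN", "left", (-4.0, 2.0, 1.0), radius=5.5)
        mask = hc.build_sphere_roi(defn, small_grid)
        assert mask.n_voxels == brute_force_sphere_count(small_grid, defn.center, defn.radius)

    def test_nine_mm_sphere_on_default_grid_matches_scan(self, phantom):
        defn = hc.ROIDefinition("s9", "ToM", "midline", (0.0, 10.0, 5.0), radius=9.0)
        mask = hc.build_sphere_roi(defn, phantom.grid)
        assert mask.n_voxels == brute_force_sphere_count(phantom.grid, defn.center, 9.0)

    def test_midline_sphere_is_x_mirror_symmetric(self, small_grid):
        defn = hc.ROIDefinition("mid", "ToM", "midline", (0.0, 1.0, 0.0), radius=5.0)
        mask = hc.build_sphere_roi(defn, small_grid)
        assert np.array_equal(mask.data, np.flip(mask.data, axis=0))

    def test_sphere_outside_grid_raises(self, small_grid):
        defn = hc.ROIDefinition("out", "ToM", "left", (-500.0, 0.0, 0.0), radius=3.0)
        with pytest.raises(ValueError, match="outside"):
            hc.build_sphere_roi(defn, small_grid)


class TestHemispheres:
    def test_left_right_disjoint_and_partition(self, small_grid):
        left = hc.hemisphere_mask(small_grid, "left")
        right = hc.hemisphere_mask(small_grid, "right")
        assert not (left.data & right.data).any()
        midplane = np.zeros(small_grid.dims, dtype=bool)
        midplane[np.isclose(small_grid.axis_coords(0), 0.0), :, :] = True
        assert (left.data | right.data | midplane).all()

    def test_symmetric_grid_has_equal_hemispheres(self, small_grid):
        assert (
            hc.hemisphere_mask(small_grid, "left").n_voxels
            == hc.hemisphere_mask(small_grid, "right").n_voxels
        )

    def test_restriction_partition_counts(self, small_grid):
        defn = hc.ROIDefinition("mid", "ToM", "midline", (1.0, 0.0, 0.0), radius=6.0)
        roi = hc.build_sphere_roi(defn, small_grid)
        left = hc.restrict_to_hemisphere(roi, "left")
        right = hc.restrict_to_hemisphere(roi, "right")
        on_plane = roi.data[np.isclose(small_grid.axis_coords(0), 0.0), :, :].sum()
        assert left.n_voxels + right.n_voxels + on_plane == roi.n_voxels

    def test_one_sided_roi_restriction_identity_and_empty(self, small_grid):
        defn = hc.ROIDefinition("l", "PAIN", "left", (-6.0, 0.0, 0.0), radius=3.0)
        roi = hc.build_sphere_roi(defn, small_grid)
        same = hc.restrict_to_hemisphere(roi, "left")
        assert np.array_equal(same.data, roi.data)
        empty = hc.restrict_to_hemisphere(roi, "right")
        assert empty.n_voxels == 0 and empty.degenerate


class TestMirror:
    def test_single_voxel_reflects(self, small_grid):
        data = np.zeros(small_grid.dims, dtype=bool)
        data[0, 2, 3] = True  # world x = -10
        roi = hc.ROIMask(data, small_grid, "v")
        mirrored = hc.mirror_across_midline(roi)
        assert mirrored.data[10, 2, 3] and mirrored.n_voxels == 1

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_involution_and_count_conservation(self, small_grid, seed):
        rng = np.random.default_rng(seed)
        data = rng.random(small_grid.dims) < 0.3
        roi = hc.ROIMask(data, small_grid, "rand", degenerate=not data.any())
        mirrored = hc.mirror_across_midline(roi)
        assert mirrored.n_voxels == roi.n_voxels
        assert np.array_equal(hc.mirror_across_midline(mirrored).data, roi.data)

    def test_left_mask_mirrors_into_right_hemisphere(self, small_grid):
        defn = hc.ROIDefinition("mid", "ToM", "midline", (0.0, 0.0, 0.0), radius=6.0)
        left = hc.restrict_to_hemisphere(hc.build_sphere_roi(defn, small_grid), "left")
        mirrored = hc.mirror_across_midline(left)
        right_hemi = hc.hemisphere_mask(small_grid, "right")
        assert not (mirrored.data & ~right_hemi.data).any()

    def test_asymmetric_grid_rejected(self):
        grid = hc.ImageGrid((4, 4, 4), 2.0, (0.0, 0.0, 0.0))
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 1, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            hc.mirror_across_midline(hc.ROIMask(data, grid, "x"))


class TestLateralizedSets:
    def test_left_variant_membership(self, bilateral_set):
        left = hc.make_lateralized_set(bilateral_set, "left")
        assert "LTPJ" in left.masks and "RTPJ" not in left.masks
        assert {"dMPFC", "mMPFC", "vMPFC", "PC", "AMCC"} <= set(left.masks)
        assert {"LInsula", "LMFG", "LS2"} <= set(left.masks)

    def test_right_variant_midline_count_set_arithmetic(self, small_grid):
        # hand-built asymmetric "midline" mask: 3 left voxels, 1 right voxel,
        # with one mirrored left voxel coinciding with the right voxel
        data = np.zeros(small_grid.dims, dtype=bool)
        data[3, 4, 3] = True  # x=-4 -> mirrors to index 7
        data[4, 4, 3] = True  # x=-2 -> mirrors to index 6
        data[2, 2, 2] = True  # x=-6 -> mirrors to index 8
        data[7, 4, 3] = True  # x=+4, coincides with mirror of index 3
        roi = hc.ROIMask(data, small_grid, "M")
        rs = hc.ROISet(variant="bilateral", masks={"M": roi, "pad_a": roi_at(small_grid, 1), "pad_b": roi_at(small_grid, 9)})
        right = hc.make_lateralized_set(rs, "right")
        # |orig ∩ RH| + |mirror(orig ∩ LH)| - |overlap| = 1 + 3 - 1
        assert right.masks["M"].n_voxels == 3

    def test_symmetric_midline_roi_right_variant_equals_right_half(self, small_grid):
        defn = hc.ROIDefinition("mid", "ToM", "midline", (0.0, 0.0, 0.0), radius=6.0)
        roi = hc.build_sphere_roi(defn, small_grid)
        rs = hc.ROISet(variant="bilateral", masks={"mid": roi})
        right = hc.make_lateralized_set(rs, "right")
        expected = hc.restrict_to_hemisphere(roi, "right")
        assert np.array_equal(right.masks["mid"].data, expected.data)

    def test_bilateral_variant_is_identity(self, bilateral_set):
        assert hc.make_lateralized_set(bilateral_set, "bilateral") is bilateral_set

    def test_all_masks_share_grid_after_lateralization(self, bilateral_set):
        for variant in ("left", "right"):
            vset = hc.make_lateralized_set(bilateral_set, variant)
            g = vset.grid
            assert all(m.grid.dims == g.dims for m in vset.masks.values())


def roi_at(grid, x_index):
    data = np.zeros(grid.dims, dtype=bool)
    data[x_index, 0, 0] = True
    return hc.ROIMask(data, grid, f"at{x_index}")


class TestSoftMaskAndResample:
    def test_sigma_zero_is_hard_mask(self, small_grid):
        anatomy = np.ones(small_grid.dims)
        w = rois.soft_hemisphere_mask(anatomy, small_grid, "left", sigma_mm=0.0)
        hard = hc.hemisphere_mask(small_grid, "left").data.astype(float)
        assert np.array_equal(w, hard)
        masked = rois.apply_soft_mask(anatomy, w)
        assert (masked[small_grid.axis_coords(0) > 0, :, :] == 0).all()

    def test_weights_saturate_deep_inside_kept_hemisphere(self, phantom):
        anatomy = np.ones(phantom.grid.dims)
        w = rois.soft_hemisphere_mask(anatomy, phantom.grid, "left", sigma_mm=0.5)
        deep_left = phantom.grid.axis_coords(0) < -5 * 0.5 - phantom.grid.voxel_size
        assert np.allclose(w[deep_left, 1:-1, 1:-1], 1.0, atol=1e-6)

    def test_mass_never_increases(self, small_grid):
        rng = np.random.default_rng(0)
        anatomy = rng.random(small_grid.dims)
        w = rois.soft_hemisphere_mask((anatomy > 0).astype(float), small_grid, "right")
        assert rois.apply_soft_mask(anatomy, w).sum() <= anatomy.sum() + 1e-12

    def test_resample_identity_on_same_grid(self, small_grid):
        rng = np.random.default_rng(1)
        binary = (rng.random(small_grid.dims) < 0.4).astype(float)
        mask = rois.resample_binarize(binary, small_grid, small_grid)
        assert np.array_equal(mask.data, binary.astype(bool))

    def test_threshold_tie_rule(self, small_grid):
        half = np.full(small_grid.dims, 0.5)
        assert rois.resample_binarize(half, small_grid, small_grid).data.all()
        below = np.full(small_grid.dims, 0.49)
        mask = rois.resample_binarize(below, small_grid, small_grid)
        assert mask.n_voxels == 0 and mask.degenerate


class TestNiftiRoundTrip:
    def test_mask_round_trip(self, small_grid, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.random(small_grid.dims) < 0.5
        path = tmp_path / "mask.nii.gz"
        rois.save_volume(data, small_grid, path)
        loaded, grid = rois.load_volume(path)
        assert np.array_equal(loaded.astype(bool), data)
        assert grid.dims == small_grid.dims
        assert np.allclose(grid.origin, small_grid.origin)

    def test_roi_definition_table_round_trip(self, roi_definitions, tmp_path):
        path = tmp_path / "rois.tsv"
        rois.write_roi_definitions(roi_definitions, path)
        back = rois.read_roi_definitions(path)
        assert back == roi_definitions
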