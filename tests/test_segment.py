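"""Threshold, erosion, labelling and per-pellet summarisation."""

import numpy as np
import pytest
from scipy import ndimage

from pelletdei import (
    DEIVolume,
    SegmentationConfig,
    erode_mask,
    label_pellets,
    pellet_dei_stats,
    threshold_mask,
)
from pelletdei.segment import disk_footprint, packaged_disk4_footprint

from helpers import erode_2d_bruteforce, label_floodfill

CFG = SegmentationConfig()


class TestThreshold:
    def test_background_block_is_empty(self):
        assert not threshold_mask(np.full((3, 3, 3), 60.0), CFG).any()

    def test_comparison_is_strict(self):
        grid = np.array([[[1999.9, 2000.0, 2000.1]]])
        np.testing.assert_array_equal(
            threshold_mask(grid, CFG), [[[False, False, True]]]
        )

    def test_nonfinite_input_rejected(self):
        grid = np.full((2, 2, 2), 100.0)
        grid[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            threshold_mask(grid, CFG)


class TestErosion:
    def test_packaged_footprint_matches_euclidean_definition(self):
        fp = packaged_disk4_footprint()
        np.testing.assert_array_equal(fp, disk_footprint(4))
        assert fp.sum() == 13 and fp.shape == (5, 5)

    def test_empty_and_single_voxel(self):
        empty = np.zeros((8, 8, 3), dtype=bool)
        assert not erode_mask(empty, CFG).any()
        single = empty.copy()
        single[4, 4, 1] = True
        assert not erode_mask(single, CFG).any()

    def test_square_matches_bruteforce_oracle(self):
        mask3d = np.zeros((16, 16, 1), dtype=bool)
        mask3d[3:13, 3:13, 0] = True
        got = erode_mask(mask3d, CFG)[:, :, 0]
        want = erode_2d_bruteforce(mask3d[:, :, 0], disk_footprint(4))
        np.testing.assert_array_equal(got, want)
        assert got.sum() > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_masks_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((18, 18)) < 0.6
        got = erode_mask(mask[:, :, None], CFG)[:, :, 0]
        np.testing.assert_array_equal(got, erode_2d_bruteforce(mask, disk_footprint(4)))

    def test_erosion_is_subset_and_slicewise(self):
        rng = np.random.default_rng(1)
        mask = rng.random((12, 12, 4)) < 0.7
        out = erode_mask(mask, CFG)
        assert not (out & ~mask).any()
        # slices are independent: eroding each slice alone gives the same result
        for k in range(mask.shape[2]):
            np.testing.assert_array_equal(
                out[:, :, k], erode_mask(mask[:, :, [k]], CFG)[:, :, 0]
            )

    def test_slice_axis_follows_config(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 4, 10)) < 0.7
        out = erode_mask(mask, SegmentationConfig(slice_axis=1))
        ref = erode_mask(np.moveaxis(mask, 1, 2), CFG)
        np.testing.assert_array_equal(out, np.moveaxis(ref, 2, 1))


class TestLabelling:
    def test_empty_mask_has_no_components(self):
        labels, census = label_pellets(np.zeros((5, 5, 5), dtype=bool), CFG)
        assert census == {} and not labels.any()

    def test_separated_and_overlapping_spheres(self):
        x, y, z = np.mgrid[0:24, 0:24, 0:24]
        far = ((x - 6) ** 2 + (y - 6) ** 2 + (z - 6) ** 2 <= 9) | (
            (x - 17) ** 2 + (y - 17) ** 2 + (z - 17) ** 2 <= 9
        )
        _, census = label_pellets(far, CFG)
        assert len(census) == 2
        touching = ((x - 6) ** 2 + (y - 6) ** 2 + (z - 6) ** 2 <= 9) | (
            (x - 10) ** 2 + (y - 6) ** 2 + (z - 6) ** 2 <= 9
        )
        _, census = label_pellets(touching, CFG)
        assert len(census) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_random_masks_match_floodfill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 10)) < 0.25
        cfg = SegmentationConfig(connectivity=connectivity)
        labels, census = label_pellets(mask, cfg)
        oracle_labels, n = label_floodfill(mask, connectivity)
        assert len(census) == n
        # same partition: one-to-one correspondence of label sets
        for lab in census:
            voxels = labels == lab
            assert len(np.unique(oracle_labels[voxels])) == 1
        assert sum(census.values()) == int(mask.sum())

    def test_min_core_voxels_and_size_hook(self):
        mask = np.zeros((10, 10, 3), dtype=bool)
        mask[1:3, 1:3, 0] = True  # 4 voxels
        mask[6, 6, 2] = True  # singleton
        _, census = label_pellets(mask, SegmentationConfig(min_core_voxels=2))
        assert sorted(census.values()) == [4]
        _, census = label_pellets(mask, SegmentationConfig(max_voxel_count=2))
        assert sorted(census.values()) == [1]


class TestPelletStats:
    def _dei(self, grid, valid=None, spacing=(1.0, 1.0, 1.0)):
        valid = np.ones_like(grid, bool) if valid is None else valid
        return DEIVolume(dei=grid, valid_mask=valid, spacing=spacing)

    def test_uniform_region_mean_and_sd(self):
        grid = np.full((4, 4, 1), 0.2)
        labels = np.ones_like(grid, dtype=int)
        (rec,) = pellet_dei_stats(labels, self._dei(grid))
        assert rec.mean_dei == pytest.approx(0.2)
        assert rec.sd_dei == 0.0
        assert rec.voxel_count == 16

    def test_two_value_component_and_centroid_scaling(self):
        grid = np.zeros((2, 1, 1))
        grid[0, 0, 0], grid[1, 0, 0] = 0.1, 0.3
        labels = np.ones_like(grid, dtype=int)
        (rec,) = pellet_dei_stats(labels, self._dei(grid, spacing=(2.0, 1.0, 1.0)))
        assert rec.mean_dei == pytest.approx(0.2)
        assert rec.centroid_mm == pytest.approx((1.0, 0.0, 0.0))

    def test_all_invalid_component_is_excluded_with_warning(self, caplog):
        grid = np.full((2, 2, 1), 0.5)
        labels = np.ones_like(grid, dtype=int)
        labels[1, :, :] = 2
        valid = np.ones_like(grid, bool)
        valid[1, :, :] = False
        with caplog.at_level("WARNING"):
            records = pellet_dei_stats(labels, self._dei(grid, valid))
        assert [r.label for r in records] == [1]
        assert "no valid DEI voxels" in caplog.text

    def test_mean_uses_only_valid_voxels(self):
        grid = np.array([[[0.1, 0.9]]])
        valid = np.array([[[True, False]]])
        labels = np.ones_like(grid, dtype=int)
        (rec,) = pellet_dei_stats(labels, self._dei(grid, valid))
        assert rec.mean_dei == pytest.approx(0.1)
        assert rec.voxel_count == 2  # size counts all voxels of the component
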