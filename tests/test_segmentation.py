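import numpy as np
import pytest
from scipy import ndimage

from subcelldist.image_io import VoxelGrid
from subcelldist.segmentation import (
    SegmentationParams,
    filter_min_volume,
    log_response,
    normalize_intensity,
    segment_structure,
    split_touching,
    spot_filter_3d,
)


def grid(data, voxel=(0.3, 0.1, 0.1)):
    return VoxelGrid(np.asarray(data, dtype=float), voxel)


class TestNormalize:
    def test_full_range_is_linear_rescale(self):
        img = grid(np.arange(101, dtype=float).reshape(1, 1, 101))
        out = normalize_intensity(img, (0, 100))
        np.testing.assert_allclose(out.data.ravel(), np.arange(101) / 100.0)

    def test_values_above_high_percentile_clip_to_one(self):
        data = np.zeros((1, 10, 10))
        data[0, 0, 0] = 100.0
        data[0, 5, 5] = 1.0
        out = normalize_intensity(grid(data), (0, 90))
        assert out.data[0, 0, 0] == 1.0

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(grid(np.full((2, 4, 4), 7.0)))

    def test_monotone_within_window(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(size=(4, 16, 16))
        out = normalize_intensity(grid(data), (0, 100)).data
        order = np.argsort(data.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)


class TestSpotFilter:
    def make_gaussian_volume(self, sigma=(1.0, 1.5, 1.5), shape=(15, 31, 31)):
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        c = [s // 2 for s in shape]
        r2 = sum(((a - ci) / si) ** 2 for a, ci, si in zip((zz, yy, xx), c, sigma))
        return np.exp(-0.5 * r2), tuple(c)

    def test_gaussian_spot_peak_in_mask(self):
        # oracle: the LoG response of an analytic Gaussian peaks at its center
        data, center = self.make_gaussian_volume()
        resp = log_response(data, (1.0, 1.5, 1.5))
        assert tuple(np.unravel_index(resp.argmax(), resp.shape)) == center
        params = SegmentationParams(
            spot_filter_scale=(1.0, 1.5, 1.5),
            spot_filter_cutoff=resp.max() * 0.5,
            spot_filter_extend_cutoff=None,
        )
        mask = spot_filter_3d(grid(data), params)
        assert mask.data[center]

    def test_noise_null_calibrated_cutoff_gives_empty_mask(self):
        # Monte-Carlo null: cutoff above the max null response => no detections
        rng = np.random.default_rng(42)
        null = rng.normal(0, 1, size=(10, 64, 64))
        null_resp = log_response(null, (0.9, 1.2, 1.2))
        cutoff = null_resp.max() * 1.01
        test = rng.normal(0, 1, size=(10, 64, 64))
        params = SegmentationParams(spot_filter_cutoff=cutoff, spot_filter_extend_cutoff=None)
        mask = spot_filter_3d(grid(np.abs(test)), params)
        # same-scale noise: expect (near-)empty mask; allow the odd voxel
        assert mask.foreground_count() <= 3

    def test_minus_inf_cutoff_selects_everything(self):
        params = SegmentationParams(spot_filter_cutoff=-np.inf)
        data = np.random.default_rng(0).uniform(size=(4, 8, 8))
        mask = spot_filter_3d(grid(data), params)
        assert mask.foreground_count() == data.size

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SegmentationParams(spot_filter_scale=0.0)


class TestWatershed:
    def dumbbell(self):
        # two Gaussian peaks sharing a thin neck
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in (9, 15, 31)], indexing="ij")
        g1 = np.exp(-0.5 * (((zz - 4) / 1.5) ** 2 + ((yy - 7) / 2) ** 2 + ((xx - 10) / 2) ** 2))
        g2 = np.exp(-0.5 * (((zz - 4) / 1.5) ** 2 + ((yy - 7) / 2) ** 2 + ((xx - 20) / 2) ** 2))
        data = g1 + g2
        mask = data > 0.1
        return grid(data), mask

    def test_dumbbell_splits_into_two(self):
        img, mask = self.dumbbell()
        labels = split_touching(mask, img)
        assert labels.max() == 2
        # each label contains one true peak
        assert labels[4, 7, 10] != labels[4, 7, 20]
        assert labels[4, 7, 10] > 0 and labels[4, 7, 20] > 0

    def test_watershed_conserves_foreground(self):
        img, mask = self.dumbbell()
        labels = split_touching(mask, img)
        assert (labels > 0).sum() == mask.sum()
        np.testing.assert_array_equal(labels > 0, mask)

    def test_separated_spots_stay_separate(self):
        data = np.zeros((5, 10, 30))
        data[2, 5, 5] = data[2, 5, 25] = 1.0
        data = ndimage.gaussian_filter(data, 1.2)
        mask = data > data.max() * 0.2
        labels = split_touching(mask, grid(data))
        assert labels.max() == 2

    def test_single_blob_one_label(self):
        data = np.zeros((7, 15, 15))
        data[3, 7, 7] = 1.0
        data = ndimage.gaussian_filter(data, 1.5)
        mask = data > data.max() * 0.2
        labels = split_touching(mask, grid(data))
        assert labels.max() == 1

    def test_empty_mask_gives_empty_labels(self):
        labels = split_touching(np.zeros((3, 4, 4), dtype=bool), grid(np.ones((3, 4, 4))))
        assert labels.max() == 0


class TestMinVolume:
    def make_labels(self, volumes):
        lab = np.zeros((1, 4, sum(volumes) + len(volumes)), dtype=np.int32)
        x = 0
        for i, v in enumerate(volumes, start=1):
            lab[0, 0, x : x + v] = i
            x += v + 1
        return lab

    def test_threshold_counts(self):
        lab = self.make_labels([5, 30, 200])
        out = filter_min_volume(lab, 20)
        assert out.max() == 2
        assert sorted(np.bincount(out.ravel())[1:]) == [30, 200]

    def test_threshold_one_is_identity(self):
        lab = self.make_labels([3, 7])
        np.testing.assert_array_equal(filter_min_volume(lab, 1), lab)

    def test_threshold_above_everything_empties(self):
        lab = self.make_labels([3, 7])
        assert filter_min_volume(lab, 1000).max() == 0

    def test_survivors_relabeled_consecutively(self):
        lab = self.make_labels([5, 30, 4, 50])
        out = filter_min_volume(lab, 20)
        assert set(np.unique(out)) == {0, 1, 2}


def test_full_chain_deterministic():
    from subcelldist.synthetic import random_scene, render_scene

    spec = random_scene(15, 2, seed=7, snr=5)
    g1, _, _ = render_scene(spec)
    a = segment_structure(g1)
    b = segment_structure(g1)
    np.testing.assert_array_equal(a, b)
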