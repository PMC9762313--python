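"""Detection core vs independent oracles, plus its algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import flood_fill_label, otsu_exhaustive, window_median, window_variance
from pcquant.errors import DegenerateHistogramError, ValidationError
from pcquant.image_model import ImageStack, Mask
from pcquant.segment import (
    DetectionParams,
    binarize,
    compute_threshold,
    detect,
    fill_holes,
    filter_objects,
    gaussian_filter,
    label_components,
    median_filter_2d,
    otsu_threshold,
    relabel_canonical,
    rolling_ball_subtract,
    variance_filter,
    watershed_split,
)


class TestFilters:
    def test_median_constant_unchanged(self):
        img = np.full((10, 10), 7.0)
        np.testing.assert_array_equal(median_filter_2d(img, 1), img)

    def test_median_removes_hot_pixel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        out = median_filter_2d(img, 1)
        assert out[4, 4] == 0.0

    def test_median_matches_window_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(32, 32))
        for radius in (1, 2):
            np.testing.assert_allclose(
                median_filter_2d(img, radius), window_median(img, radius)
            )

    def test_median_per_slice_on_zstack(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 10, size=(3, 8, 8))
        out = median_filter_2d(vol, 1)
        for z in range(3):
            np.testing.assert_allclose(out[z], median_filter_2d(vol[z], 1))

    def test_gaussian_sigma_zero_identity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(6, 6))
        np.testing.assert_array_equal(gaussian_filter(img, 0.0), img)

    def test_gaussian_constant_unchanged(self):
        img = np.full((12, 12), 3.0)
        np.testing.assert_allclose(gaussian_filter(img, 2.0), img)

    def test_gaussian_kernel_normalized(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = gaussian_filter(img, 2.0)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_variance_constant_is_zero(self):
        img = np.full((8, 8), 9.0)
        np.testing.assert_allclose(variance_filter(img, 1), 0.0, atol=1e-9)

    def test_variance_peaks_on_step_edge(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        out = variance_filter(img, 1)
        peak_cols = set(np.where(out == out.max())[1])
        assert peak_cols <= {4, 5}

    def test_variance_matches_window_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 50, size=(16, 16))
        np.testing.assert_allclose(
            variance_filter(img, 1), window_variance(img, 1), rtol=1e-9, atol=1e-7
        )

    def test_rolling_ball_flat_gives_zero(self):
        img = np.full((20, 20), 55.0)
        np.testing.assert_allclose(rolling_ball_subtract(img, 5), 0.0)

    def test_rolling_ball_preserves_narrow_peak(self):
        img = np.zeros((21, 21))
        img[10, 10] = 80.0
        out = rolling_ball_subtract(img, 5)
        assert abs(out[10, 10] - 80.0) <= 1.0

    def test_rolling_ball_removes_broad_plateau(self):
        img = np.zeros((40, 40))
        img[5:35, 5:35] = 60.0  # 30 px wide, ball radius 5
        out = rolling_ball_subtract(img, 5)
        assert out[20, 20] == 0.0


class TestThreshold:
    def test_otsu_separates_two_classes(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        t = compute_threshold(img, "otsu")
        assert 10 <= t < 200
        assert t == otsu_exhaustive(img)

    @pytest.mark.parametrize("seed", range(20))
    def test_otsu_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish random images of varying separation
        n = rng.integers(50, 400)
        img = np.concatenate([
            rng.normal(rng.uniform(20, 80), rng.uniform(1, 20), size=n),
            rng.normal(rng.uniform(100, 220), rng.uniform(1, 30), size=n),
        ])
        assert otsu_threshold(img) == otsu_exhaustive(img)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            compute_threshold(np.full((5, 5), 3.0), "otsu")

    def test_multiplier_then_clamp(self):
        img = np.zeros((2, 2))
        assert compute_threshold(img, "fixed", k=1.5, fixed=50.0) == 75.0
        assert compute_threshold(img, "fixed", k=0.5, t_min=40.0, fixed=50.0) == 40.0

    def test_mean_method(self):
        img = np.array([0.0, 10.0])
        assert compute_threshold(img, "mean") == 5.0

    def test_fractional_minimum(self):
        img = np.linspace(0, 100, 11)
        t = compute_threshold(img, "fixed", fixed=10.0, t_min=0.5,
                              t_min_fractional=True)
        assert t == 50.0

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=0.0, max_value=200.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_raising_k_or_tmin_never_adds_foreground(self, seed, k, t_min):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, size=(16, 16))
        base = binarize(img, compute_threshold(img, "otsu", k=1.0)).area_pixels
        up_k = binarize(img, compute_threshold(img, "otsu", k=1.0 + k)).area_pixels
        up_t = binarize(img, compute_threshold(img, "otsu", t_min=t_min)).area_pixels
        assert up_k <= base
        assert up_t <= base


class TestBinarize:
    def test_threshold_at_max_empty(self):
        img = np.arange(9.0).reshape(3, 3)
        assert binarize(img, img.max()).area_pixels == 0

    def test_threshold_below_min_full(self):
        img = np.arange(1, 10, dtype=float).reshape(3, 3)
        assert binarize(img, 0.0).area_pixels == 9

    def test_idempotent(self):
        img = np.arange(9.0).reshape(3, 3)
        m1 = binarize(img, 4.0)
        m2 = binarize(m1.data.astype(float), 0.5)
        np.testing.assert_array_equal(m1.data, m2.data)


class TestFillHoles:
    def test_ring_becomes_disk(self):
        m = np.zeros((11, 11), dtype=bool)
        yy, xx = np.mgrid[:11, :11]
        d = np.hypot(yy - 5, xx - 5)
        m[(d >= 2.5) & (d <= 4.5)] = True
        filled = fill_holes(Mask(m))
        assert filled.data[5, 5]
        assert filled.area_pixels > m.sum()

    def test_open_c_unchanged(self):
        m = np.zeros((9, 9), dtype=bool)
        m[2:7, 2] = True
        m[2, 2:7] = True
        m[6, 2:7] = True  # C open on the right
        np.testing.assert_array_equal(fill_holes(Mask(m)).data, m)

    def test_hollow_3d_shell_filled(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[2:7, 2:7, 2:7] = True
        m[3:6, 3:6, 3:6] = False  # internal cavity
        filled = fill_holes(Mask(m))
        assert filled.data[4, 4, 4]
        assert filled.area_pixels == 5**3


class TestLabeling:
    def test_diagonal_pixels_connectivity(self):
        m = Mask(np.array([[1, 0], [0, 1]], dtype=bool))
        assert label_components(m, connectivity=4).n_labels == 2
        assert label_components(m, connectivity=8).n_labels == 1

    def test_empty_mask(self):
        assert label_components(Mask(np.zeros((4, 4), dtype=bool))).n_labels == 0

    @pytest.mark.parametrize("connectivity,full", [(4, False), (8, True)])
    def test_matches_flood_fill_2d(self, connectivity, full):
        rng = np.random.default_rng(5)
        m = rng.random((20, 20)) < 0.45
        ours = label_components(Mask(m), connectivity).data
        oracle = flood_fill_label(m, full)
        np.testing.assert_array_equal(ours, oracle)

    @pytest.mark.parametrize("connectivity,full", [(6, False), (26, True)])
    def test_matches_flood_fill_3d(self, connectivity, full):
        rng = np.random.default_rng(6)
        m = rng.random((20, 20, 5)) < 0.35
        ours = label_components(Mask(m), connectivity).data
        oracle = flood_fill_label(m, full)
        np.testing.assert_array_equal(ours, oracle)

    def test_labels_raster_ordered(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0, 4] = True   # first in raster scan
        m[3, 0] = True
        lab = label_components(Mask(m)).data
        assert lab[0, 4] == 1
        assert lab[3, 0] == 2


class TestWatershed:
    @staticmethod
    def _disk_mask(shape, centers, r):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        m = np.zeros(shape, dtype=bool)
        for cx, cy in centers:
            m |= np.hypot(xx - cx, yy - cy) <= r
        return m

    def test_single_disk_one_object(self):
        m = self._disk_mask((21, 21), [(10, 10)], 6)
        assert watershed_split(Mask(m)).n_labels == 1

    def test_two_overlapping_disks_split(self):
        r = 8
        m = self._disk_mask((25, 41), [(14, 12), (26, 12)], r)  # 12 px apart
        labels = watershed_split(Mask(m))
        assert labels.n_labels == 2
        # split near the equidistant line x = 20 (+-1 px)
        arr = labels.data
        left = arr[:, :19]
        right = arr[:, 22:]
        assert len(np.unique(left[left > 0])) == 1
        assert len(np.unique(right[right > 0])) == 1
        assert np.unique(left[left > 0])[0] != np.unique(right[right > 0])[0]

    def test_conserves_foreground(self):
        rng = np.random.default_rng(7)
        blobs = self._disk_mask(
            (40, 40), [(10, 10), (18, 12), (30, 28)], 7
        )
        labels = watershed_split(Mask(blobs))
        np.testing.assert_array_equal(labels.data > 0, blobs)


class TestFilterObjects:
    def test_identity_with_min_one(self):
        m = Mask((np.random.default_rng(8).random((10, 10)) < 0.3))
        labels = label_components(m)
        out = filter_objects(labels, min_voxels=1)
        np.testing.assert_array_equal(out.data, labels.data)

    def test_small_object_removed(self):
        arr = np.zeros((8, 8), dtype=bool)
        arr[0, 0:5] = True   # 5 voxels
        arr[5:7, 5:7] = True  # 4 voxels
        labels = label_components(Mask(arr))
        out = filter_objects(labels, min_voxels=5)
        assert out.n_labels == 1
        assert out.data[0, 0] == 1

    def test_roi_centroid_rule(self):
        arr = np.zeros((10, 10), dtype=bool)
        arr[1:3, 1:3] = True
        arr[7:9, 7:9] = True
        roi = np.zeros((10, 10), dtype=bool)
        roi[:5, :5] = True
        labels = label_components(Mask(arr))
        out = filter_objects(labels, roi=Mask(roi))
        assert out.n_labels == 1
        assert out.data[1, 1] == 1
        assert out.data[7, 7] == 0


class TestDetect:
    def test_recovers_planted_counts(self, uptake_scene, uptake_detections):
        _, truth = uptake_scene
        cell_labels, _, pc_labels, _ = uptake_detections
        assert cell_labels.n_labels == len(truth.cell_centers)
        assert pc_labels.n_labels == len(truth.pc_centers)

    def test_zero_image_fixed_zero_threshold(self):
        stack = ImageStack(np.zeros((20, 20), dtype=np.float32), "yx", 1.0)
        labels, recs = detect(
            stack, 0, DetectionParams(threshold_method="fixed", threshold_fixed=0.0)
        )
        assert labels.n_labels == 0
        assert recs == []

    def test_deterministic(self, uptake_scene):
        stack, _ = uptake_scene
        p = DetectionParams(min_object_voxels=20)
        a, _ = detect(stack, "cells", p)
        b, _ = detect(stack, "cells", p)
        np.testing.assert_array_equal(a.data, b.data)

    def test_provenance_recorded(self, uptake_detections):
        cell_labels = uptake_detections[0]
        prov = cell_labels.provenance
        assert prov["op"] == "detect"
        assert prov["threshold_method"] == "otsu"
        assert "threshold_applied" in prov

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            DetectionParams(threshold_multiplier=-1.0)
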