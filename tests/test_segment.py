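"""Segmentation chain: FFT high-pass, directional opening, thresholds, SAC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

from thromboflow.segment import (
    BinaryMask,
    ChannelSettings,
    InvalidROIError,
    SegmentationConfig,
    compute_sac,
    fft_background_filter,
    fibrin_discriminate,
    mask_boundary,
    morphological_clean,
    overlay_qc,
    segment_channel,
    threshold_channel,
)


def exhaustive_otsu(img_u8: np.ndarray) -> int:
    """Between-class-variance-maximising threshold by brute force."""
    hist = np.bincount(img_u8.ravel(), minlength=256).astype(float)
    idx = np.arange(256)
    best, best_t = -1.0, 0
    for t in range(255):
        w0, w1 = hist[:t + 1].sum(), hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:t + 1] * idx[:t + 1]).sum() / w0
        m1 = (hist[t + 1:] * idx[t + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, t
    return best_t


class TestFFTBackgroundFilter:
    def test_constant_image_removed_exactly(self):
        out = fft_background_filter(np.full((128, 128), 87.0), 4)
        assert np.abs(out).max() < 2.0

    def test_gradient_suppressed_spot_retained(self):
        """Cross-checked against spatial-domain smoothing subtraction."""
        h = w = 256
        xx = np.arange(w)[None, :] * np.ones((h, 1))
        img = 60 + 80 * xx / (w - 1)
        img[120:125, 120:125] += 100
        out = fft_background_filter(img, 4)
        assert np.ptp(out[40, :]) <= 8.0            # >= 90 % gradient reduction
        spot = out[120:125, 120:125].max() - np.median(out[110:135, 100:115])
        assert spot >= 70.0                          # >= 70 % contrast retained
        oracle = img - gaussian_filter(img, sigma=min(h, w) / 4)
        oracle_spot = oracle[120:125, 120:125].max() \
            - np.median(oracle[110:135, 100:115])
        assert spot == pytest.approx(oracle_spot, rel=0.15)

    def test_sinusoid_above_cutoff_passes(self):
        w = 256
        xx = np.arange(w)[None, :] * np.ones((w, 1))
        img = 100 + 50 * np.sin(2 * np.pi * 8 * xx / w)  # 8 cycles, cutoff 4
        out = fft_background_filter(img, 4)
        amplitude = np.ptp(out[40, 20:230]) / 2
        assert amplitude >= 0.9 * 50

    def test_pure_gradient_mean_near_zero(self):
        xx = np.arange(256)[None, :] * np.ones((256, 1))
        out = fft_background_filter(60 + 80 * xx / 255, 4)
        assert abs(out.mean()) < 0.05 * 255

    def test_linearity(self, rng):
        img = rng.uniform(0, 255, (96, 96))
        for a in (0.25, 0.5, 2.0):
            np.testing.assert_allclose(
                fft_background_filter(a * img, 3),
                a * fft_background_filter(img, 3), atol=1.0)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            fft_background_filter(np.zeros((4, 4, 3)), 2)

    def test_zero_cutoff_is_identity(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        np.testing.assert_array_equal(fft_background_filter(img, 0), img)


class TestMorphologicalClean:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 10] = True
        assert not morphological_clean(mask, 3, 3).any()

    def test_large_square_preserved(self):
        """Exact set-morphology opening on the same raster as oracle."""
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:60, 15:65] = True
        out = morphological_clean(mask, 3, 3)
        assert abs(out.sum() - mask.sum()) / mask.sum() < 0.05
        oracle = ndimage.binary_opening(mask, np.ones((1, 3)))
        oracle = ndimage.binary_opening(oracle, np.ones((3, 1)))
        np.testing.assert_array_equal(out, oracle)

    def test_empty_mask_stays_empty(self):
        assert not morphological_clean(np.zeros((16, 16), dtype=bool), 3, 3).any()

    def test_element_larger_than_image(self):
        with pytest.raises(ValueError, match="larger than the image"):
            morphological_clean(np.zeros((8, 8), dtype=bool), 9, 1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), h=st.integers(1, 5), v=st.integers(1, 5))
    def test_opening_never_adds_pixels(self, seed, h, v):
        mask = np.random.default_rng(seed).random((40, 40)) > 0.6
        out = morphological_clean(mask, h, v)
        assert not (out & ~mask).any()

    def test_order_insensitive_on_rendered_mask(self, vehicle_tf_run):
        _, _, _, truth = vehicle_tf_run
        mask = truth.masks[-1]["bf"]
        hv = morphological_clean(mask, 3, 3)
        vh = morphological_clean(morphological_clean(mask.astype(bool),
                                                     1, 3), 3, 1)
        sac_hv = compute_sac(hv)
        sac_vh = compute_sac(vh)
        assert sac_vh == pytest.approx(sac_hv, rel=0.02)


class TestThresholdChannel:
    def test_otsu_recovers_bimodal_foreground(self, rng):
        n = 200 * 200
        fg = int(0.30 * n)
        img = np.concatenate([rng.normal(30, 5, n - fg),
                              rng.normal(180, 10, fg)])
        rng.shuffle(img)
        img = np.clip(img, 0, 255).reshape(200, 200)
        mask = threshold_channel(
            img, ChannelSettings(threshold_method="otsu", min_object_area=0))
        assert 27.0 <= compute_sac(mask.raster) <= 33.0

    def test_otsu_matches_exhaustive_search(self, rng):
        img = np.clip(np.concatenate([
            rng.normal(40, 8, 5000), rng.normal(200, 12, 3000)]), 0, 255)
        img = np.rint(img).astype(np.uint8).reshape(80, 100)
        assert threshold_otsu(img) == exhaustive_otsu(img)

    def test_constant_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="constant image"):
            mask = threshold_channel(np.full((32, 32), 99.0),
                                     ChannelSettings(threshold_method="otsu"))
        assert not mask.raster.any()

    def test_fixed_mode_strictly_above(self):
        img = np.array([[10.0, 50.0], [50.0, 120.0]])
        s = ChannelSettings(threshold_method="fixed", fixed_threshold=50.0,
                            min_object_area=0)
        np.testing.assert_array_equal(
            threshold_channel(img, s).raster,
            np.array([[False, False], [False, True]]))

    def test_small_objects_removed(self):
        img = np.zeros((64, 64))
        img[5, 5] = 255.0                 # single bright pixel
        img[20:40, 20:40] = 255.0
        s = ChannelSettings(threshold_method="fixed", fixed_threshold=100,
                            min_object_area=4)
        mask = threshold_channel(img, s, pixel_size_um=0.108)
        assert not mask.raster[5, 5]
        assert mask.raster[25, 25]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           t1=st.integers(0, 254), t2=st.integers(0, 254))
    def test_sac_monotone_in_threshold(self, seed, t1, t2):
        img = np.random.default_rng(seed).uniform(0, 255, (32, 32))
        lo, hi = sorted((t1, t2))
        s_lo = ChannelSettings(threshold_method="fixed", fixed_threshold=lo,
                               min_object_area=0)
        s_hi = ChannelSettings(threshold_method="fixed", fixed_threshold=hi,
                               min_object_area=0)
        assert compute_sac(threshold_channel(img, s_hi).raster) <= \
            compute_sac(threshold_channel(img, s_lo).raster)


class TestFibrinDiscrimination:
    def test_fibres_only_recovered(self, quarter_render):
        from thromboflow.kinetics import FlowRunConfig, KineticState
        from thromboflow.render import render_images
        st_ = KineticState(time=8, platelet_coverage=0.4, thrombus_coverage=0.3,
                           ps_coverage=0.05, fibrin_coverage=0.15,
                           contraction_level=1.0, multilayer_level=1.0)
        images, truth = render_images([st_], FlowRunConfig(seed=23),
                                      quarter_render)
        mask = fibrin_discriminate(images[0].images["af647"],
                                   SegmentationConfig(),
                                   quarter_render.pixel_size_um)
        est = compute_sac(mask.raster)
        assert est == pytest.approx(truth.true_sac("af647", 0), abs=3.0)

    def test_haze_only_below_threshold(self, quarter_render):
        from thromboflow.kinetics import FlowRunConfig, KineticState
        from thromboflow.render import render_images
        st_ = KineticState(time=2, platelet_coverage=0.4, thrombus_coverage=0.3,
                           ps_coverage=0.05, fibrin_coverage=0.0,
                           contraction_level=1.0, multilayer_level=1.0)
        images, _ = render_images([st_], FlowRunConfig(seed=23), quarter_render)
        mask = fibrin_discriminate(images[0].images["af647"],
                                   SegmentationConfig(),
                                   quarter_render.pixel_size_um)
        assert compute_sac(mask.raster) < 1.0

    def test_threshold_monotonicity(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        sacs = []
        for thr in (0.0, 60.0, 120.0, 200.0):
            cfg = SegmentationConfig(fibrin_high_threshold=thr)
            sacs.append(compute_sac(fibrin_discriminate(img, cfg).raster))
        assert sacs == sorted(sacs, reverse=True)
        assert sacs[0] > 95.0  # threshold 0: nearly the whole image


class TestComputeSAC:
    def test_extremes(self):
        assert compute_sac(np.ones((10, 10), dtype=bool)) == 100.0
        assert compute_sac(np.zeros((10, 10), dtype=bool)) == 0.0

    def test_native_raster_pixel_count(self):
        mask = np.zeros(1360 * 1024, dtype=bool)
        mask[:139_264] = True
        assert compute_sac(mask.reshape(1024, 1360)) == pytest.approx(10.0)

    def test_roi_restriction(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5, :] = True
        assert compute_sac(mask, roi=(0, 5, 0, 10)) == 100.0
        assert compute_sac(mask, roi=(5, 10, 0, 10)) == 0.0

    def test_empty_roi(self):
        with pytest.raises(InvalidROIError):
            compute_sac(np.ones((10, 10), dtype=bool), roi=(5, 5, 0, 10))


class TestOverlayQC:
    def test_empty_mask_is_plain_grayscale(self, rng):
        img = rng.uniform(0, 255, (32, 32)).astype(np.uint8)
        overlay = overlay_qc(img, np.zeros((32, 32), dtype=bool))
        for c in range(3):
            np.testing.assert_array_equal(overlay[..., c], img)

    def test_full_mask_contours_border(self):
        img = np.full((16, 16), 128, dtype=np.uint8)
        overlay = overlay_qc(img, np.ones((16, 16), dtype=bool))
        assert (overlay[0, :, 0] == 255).all()   # red contour on top row
        assert (overlay[8, 8] == [128, 128, 128]).all()

    def test_contour_matches_boundary_oracle(self, vehicle_tf_run):
        _, _, image_sets, truth = vehicle_tf_run
        mask = truth.masks[-1]["bf"]
        img = image_sets[-1].images["bf"]
        overlay = overlay_qc(img, mask)
        # oracle: mask pixels with any 8-neighbour outside the mask
        padded = np.pad(mask, 1)
        neigh_out = np.zeros_like(mask)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                neigh_out |= ~padded[1 + dr:1 + dr + mask.shape[0],
                                     1 + dc:1 + dc + mask.shape[1]]
        oracle = mask & neigh_out
        np.testing.assert_array_equal(mask_boundary(mask), oracle)
        colored = (overlay[..., 0] == 255) & (overlay[..., 1] == 40)
        np.testing.assert_array_equal(colored, oracle)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            overlay_qc(np.zeros((8, 8)), np.zeros((9, 9), dtype=bool))

    def test_writes_png(self, tmp_path, rng):
        img = rng.uniform(0, 255, (16, 16)).astype(np.uint8)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        path = tmp_path / "qc.png"
        overlay_qc(img, mask, path)
        assert path.exists() and path.stat().st_size > 0


class TestFullChannelChain:
    def test_dioc6_sac_recovered_at_20_percent(self, quarter_render, seg_config):
        from thromboflow.kinetics import FlowRunConfig, KineticState
        from thromboflow.render import render_images
        st_ = KineticState(time=6, platelet_coverage=0.20, thrombus_coverage=0.12,
                           ps_coverage=0.03, fibrin_coverage=0.0,
                           contraction_level=1.0, multilayer_level=1.0)
        images, truth = render_images([st_], FlowRunConfig(seed=31),
                                      quarter_render)
        mask = segment_channel(images[0].images["dioc6"], "dioc6", seg_config,
                               quarter_render.pixel_size_um)
        assert compute_sac(mask.raster) == pytest.approx(
            truth.true_sac("dioc6", 0), abs=5.0)

    def test_binary_mask_validates_dimensionality(self):
        with pytest.raises(ValueError, match="2-D"):
            BinaryMask(np.zeros(10), channel="bf")
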