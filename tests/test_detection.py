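"""Unit and property tests for the per-frame detection chain."""

import numpy as np
import pytest
from scipy import ndimage

from clecount import (
    CalibrationError,
    DetectionParams,
    Frame,
    SimulationConfig,
    calibrate_se_radius,
    compute_granulometry,
    count_frame,
    double_threshold,
    enhance_contrast,
    iter_video_frames,
    label_and_filter,
    open_frame,
    score_detections,
)
from conftest import full_fov, place_disks


class TestEnhanceContrast:
    def test_all_zero_frame_maps_to_zero(self):
        out = enhance_contrast(full_fov(np.zeros((32, 32))), 1.0, 99.5)
        assert np.all(out.pixels == 0)

    def test_full_range_stretch_is_linear_rescale(self):
        img = np.arange(101, dtype=float).reshape(1, 101).repeat(8, axis=0)
        out = enhance_contrast(full_fov(img), 0.0, 99.99999)
        np.testing.assert_allclose(out.pixels, img / 100.0, atol=1e-6)

    def test_bright_blob_peak_saturates_to_one(self):
        # blob peak far above the 99.5th percentile of the frame
        rng = np.random.default_rng(0)
        img = rng.normal(10.0, 1.0, (128, 128)).clip(min=0)
        rr, cc = np.mgrid[:128, :128]
        img += 50.0 * np.exp(-(((rr - 64) ** 2 + (cc - 64) ** 2) / 18.0))
        out = enhance_contrast(full_fov(img), 1.0, 99.5)
        assert out.pixels[64, 64] == 1.0
        assert out.pixels.min() == 0.0 and out.pixels.max() == 1.0

    def test_percentiles_over_fov_only(self):
        img = np.full((32, 32), 5.0)
        img[:16] = 100.0  # bright half outside the mask must not matter
        mask = np.zeros((32, 32), dtype=bool)
        mask[16:] = True
        out = enhance_contrast(Frame(img, fov_mask=mask), 1.0, 99.0)
        assert np.all(out.pixels[16:] == 0)  # constant inside FOV -> zeros

    def test_invalid_percentile_order(self):
        with pytest.raises(ValueError):
            enhance_contrast(full_fov(np.zeros((8, 8))), 50.0, 10.0)


class TestOpenFrame:
    def test_anti_extensive_and_idempotent_on_random_images(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            img = rng.random((48, 48)) * 10
            opened = open_frame(full_fov(img), 2)
            assert np.all(opened.pixels <= img + 1e-12)
            reopened = open_frame(opened, 2)
            np.testing.assert_allclose(reopened.pixels, opened.pixels, atol=1e-12)

    def test_isolated_pixel_removed(self):
        img = np.zeros((21, 21))
        img[10, 10] = 7.0
        opened = open_frame(full_fov(img), 2)
        assert opened.pixels[10, 10] == 0.0

    def test_large_disk_retained(self):
        img = place_disks((41, 41), [(20, 20)], radius=6)
        opened = open_frame(full_fov(img), 4)
        # grayscale opening of a binary image equals binary opening
        from skimage.morphology import disk as _disk

        expected = ndimage.binary_opening(img > 0, structure=_disk(4)).sum()
        assert opened.pixels.sum() == expected
        # most of the disk mass survives (boundary pixels may be shaved)
        assert opened.pixels.sum() >= 0.85 * img.sum()
        assert opened.pixels[20, 20] == 1.0

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            open_frame(full_fov(np.zeros((8, 8))), 0)


class TestGranulometry:
    def test_all_zero_frame_has_no_peak(self):
        prof = compute_granulometry(full_fov(np.zeros((40, 40))), 6)
        assert np.all(prof.surface_area == 0)
        assert np.all(prof.pattern_spectrum == 0)
        assert not prof.has_peak

    @pytest.mark.parametrize("radius", [3, 5, 7])
    def test_disks_peak_at_their_radius(self, radius):
        centers = [(r, c) for r in (30, 80) for c in (30, 80, 130)]
        img = place_disks((160, 160), centers, radius)
        prof = compute_granulometry(full_fov(img), 10)
        assert prof.peak_radius == radius

    def test_two_size_classes_give_two_local_maxima(self):
        img = place_disks((200, 200), [(30 + 20 * i, 30) for i in range(8)], 3)
        img += place_disks((200, 200), [(60, 120), (140, 120)], 7)
        ps = compute_granulometry(full_fov(img), 10).pattern_spectrum
        for r in (3, 7):
            assert ps[r] > ps[r - 1] and ps[r] > ps[r + 1]

    def test_surface_area_monotone_and_spectrum_conserves_mass(self):
        rng = np.random.default_rng(2)
        img = ndimage.gaussian_filter(rng.random((64, 64)), 2.0)
        prof = compute_granulometry(full_fov(img), 8)
        assert np.all(np.diff(prof.surface_area) <= 1e-9)
        assert np.all(prof.pattern_spectrum >= 0)
        np.testing.assert_allclose(
            prof.pattern_spectrum.sum(),
            prof.surface_area[0] - prof.surface_area[-1],
            atol=1e-9,
        )

    def test_max_radius_validation(self):
        with pytest.raises(ValueError):
            compute_granulometry(full_fov(np.zeros((20, 20))), 10)


class TestCalibrateSeRadius:
    def test_mode_over_disk_frames(self):
        frames = []
        for _ in range(3):
            img = place_disks((160, 160), [(40, 40), (40, 110), (110, 40)], 5)
            frames.append(full_fov(img))
        assert calibrate_se_radius(frames, 10) == 5

    def test_single_frame_single_disk(self):
        img = place_disks((100, 100), [(50, 50)], 4)
        assert calibrate_se_radius([full_fov(img)], 10) == 4

    def test_all_dark_frames_raise_calibration_error(self):
        frames = [full_fov(np.zeros((64, 64))) for _ in range(3)]
        with pytest.raises(CalibrationError):
            calibrate_se_radius(frames, 8)

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            calibrate_se_radius([], 8)

    def test_tie_breaks_toward_smaller_radius(self):
        small = full_fov(place_disks((120, 120), [(40, 40), (40, 80)], 3))
        big = full_fov(place_disks((120, 120), [(60, 60), (60, 100)], 6))
        assert calibrate_se_radius([small, big], 10) == 3


class TestDoubleThreshold:
    def _gradient_background(self):
        """Smooth row gradient 0..0.4 so quantile levels sit above most pixels."""
        return np.linspace(0.0, 0.4, 64)[:, None].repeat(64, axis=1)

    def test_flooded_low_mask_is_single_component_discarded_downstream(self):
        # on a near-constant frame the low quantile equals the background
        # value, the candidate mask floods, and the single giant
        # component is removed by the area filter downstream
        img = np.full((32, 32), 0.1)
        img[5, 5] = 0.2
        frame = full_fov(img)
        mask = double_threshold(frame, 0.999, 0.9999)
        from skimage import measure

        assert measure.label(mask, connectivity=2).max() == 1
        det = label_and_filter(mask, frame,
                               DetectionParams(se_radius=2, min_area=5, max_area=500))
        assert det.count == 0

    def test_blob_with_seed_includes_skirt(self):
        img = self._gradient_background()
        img[8:18, 8:18] = 0.55  # skirt above L
        img[11:15, 11:15] = 0.95  # core above H
        mask = double_threshold(full_fov(img), 0.97, 0.997)
        assert mask[12, 12]  # core
        assert mask[8, 8]  # skirt pulled in by hysteresis
        assert not mask[0, 0]
        # brightest background rows exceed L but carry no seed
        assert not mask[63, :].any()

    def test_blob_without_seed_excluded(self):
        img = self._gradient_background()
        img[8:18, 8:18] = 0.55  # entirely between L and H
        img[50, 50] = 0.95  # lone seed elsewhere
        mask = double_threshold(full_fov(img), 0.97, 0.9999)
        assert not mask[8:18, 8:18].any()  # defining hysteresis behavior
        assert mask[50, 50]
        assert mask.sum() == 1

    def test_degenerate_levels_fall_back_to_single_threshold(self):
        img = np.full((32, 32), 0.3)
        mask = double_threshold(full_fov(img), 0.5, 0.9)
        assert mask.all()  # every pixel >= H == the constant

    def test_mask_false_outside_fov(self):
        img = self._gradient_background()
        img[8:18, 8:18] = 0.55
        img[11:15, 11:15] = 0.95
        fov = np.zeros((64, 64), dtype=bool)
        fov[:, 32:] = True  # blob lies outside the FOV
        mask = double_threshold(Frame(img, fov_mask=fov), 0.5, 0.99)
        assert not mask[~fov].any()


class TestLabelAndFilter:
    def test_empty_mask(self):
        mask = np.zeros((32, 32), dtype=bool)
        det = label_and_filter(mask, full_fov(np.zeros((32, 32))),
                               DetectionParams(se_radius=2, min_area=5, max_area=500))
        assert det.count == 0 and det.objects == []

    def test_round_blobs_kept_specks_discarded(self):
        img = place_disks((200, 200), [(40, 40), (40, 120), (120, 40), (120, 120), (80, 80)], 4)
        rng = np.random.default_rng(3)
        speck_pos = rng.integers(5, 195, size=(20, 2))
        for r, c in speck_pos:
            if img[r, c] == 0:
                img[r, c] = 1.0
        mask = img > 0.5
        det = label_and_filter(mask, full_fov(img),
                               DetectionParams(se_radius=2, min_area=5, max_area=500))
        assert det.count == 5
        for obj in det.objects:
            assert obj.area >= 5
            assert obj.circularity >= 0.4

    def test_thin_line_fails_circularity(self):
        img = np.zeros((64, 64))
        img[30, 10:50] = 1.0  # 40-px line: in-band area, circularity ~ 0.2
        det = label_and_filter(img > 0.5, full_fov(img),
                               DetectionParams(se_radius=2, min_area=5, max_area=500,
                                               min_circularity=0.4))
        assert det.count == 0

    def test_area_band_enforced(self):
        img = place_disks((64, 64), [(32, 32)], 5)
        params = DetectionParams(se_radius=2, min_area=5, max_area=30)  # disk area 81 > 30
        det = label_and_filter(img > 0.5, full_fov(img), params)
        assert det.count == 0

    def test_component_outside_fov_mask_discarded(self):
        img = place_disks((64, 64), [(10, 10), (40, 40)], 4)
        fov = np.zeros((64, 64), dtype=bool)
        fov[25:, 25:] = True  # only the second disk lies inside
        det = label_and_filter(img > 0.5, Frame(img, fov_mask=fov),
                               DetectionParams(se_radius=2, min_area=5, max_area=500))
        assert det.count == 1


class TestCountFrame:
    def test_all_zero_frame_counts_zero(self):
        det = count_frame(full_fov(np.zeros((128, 128))), DetectionParams(se_radius=2))
        assert det.count == 0

    def test_simulator_cells_counted_and_debris_ignored(self, small_sim_config):
        # five well-separated cells at high SNR; debris below min_area
        cfg = small_sim_config(cell_rate=5.0, persistence=1.0, debris_rate=20.0,
                               min_separation=30.0, seed=11, n_frames=2)
        # percentiles rescaled for the 256^2 test frames (the shipped
        # defaults are sized for 512^2 fields; see docs/methods.md)
        params = DetectionParams(se_radius=2, enhance_high_pct=99.0, thr_low=0.99)
        for frame, truth in iter_video_frames(cfg):
            det = count_frame(frame, params)
            score = score_detections(det.objects, truth, match_radius=5.0)
            assert score.recall == 1.0
            assert score.false_positives <= 1

    def test_scale_invariance_under_intensity_rescaling(self, small_sim_config):
        cfg = small_sim_config(seed=4, n_frames=1)
        params = DetectionParams(se_radius=2, thr_low=0.99)
        frame, _ = next(iter_video_frames(cfg))
        base = count_frame(frame, params)
        for c in (0.5, 2.0, 8.0):  # powers of two rescale exactly in floats
            scaled = Frame(frame.pixels * c, frame.fov_mask, frame.frame_index)
            det = count_frame(scaled, params)
            assert det.count == base.count
            for a, b in zip(det.objects, base.objects):
                assert (a.centroid_row, a.centroid_col, a.area) == (
                    b.centroid_row, b.centroid_col, b.area)

    def test_deterministic(self, small_sim_config):
        cfg = small_sim_config(seed=5, n_frames=1)
        params = DetectionParams(se_radius=2, thr_low=0.99)
        frame, _ = next(iter_video_frames(cfg))
        d1 = count_frame(frame, params)
        d2 = count_frame(frame, params)
        assert d1.count == d2.count
        assert [o.centroid_row for o in d1.objects] == [o.centroid_row for o in d2.objects]

    def test_tophat_variant_detects_cells_with_band_pass(self, small_sim_config):
        # the band-pass switch trades accuracy for background
        # suppression; it must still find cells, though with lower
        # recall than the default opening path
        cfg = small_sim_config(cell_rate=4.0, persistence=1.0, min_separation=40.0,
                               seed=6, n_frames=4)
        params = DetectionParams(se_radius=2, enhance_high_pct=99.5, thr_low=0.99,
                                 thr_high=0.999, tophat=True)
        tp = fn = 0
        for frame, truth in iter_video_frames(cfg):
            det = count_frame(frame, params)
            s = score_detections(det.objects, truth, match_radius=5.0)
            tp += s.true_positives
            fn += s.false_negatives
        assert tp / (tp + fn) >= 0.5
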