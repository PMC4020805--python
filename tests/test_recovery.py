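"""Exposure calibration against in-frame standards and reflectance output."""

import numpy as np
import pytest

import floralcam as fc
from floralcam.camera import NoiseSpec, exposure_for_white
from conftest import uniform_calibrated


def _frame_with_standards(values, rois, shape=(96, 96), n_channels=1):
    """Linear CalibratedImage with constant patches at given ROIs."""
    img = uniform_calibrated(0.1, shape, n_channels)
    for (r0, r1, c0, c1), v in zip(rois, values):
        img.channels[r0:r1, c0:c1, :] = v
    return img


WHITE_ROI = (10, 30, 10, 30)
GREY_ROI = (10, 30, 50, 70)


class TestCalibrateExposure:
    def test_grey_standard_reading_its_nominal_gives_unit_scale(self):
        img = _frame_with_standards([0.33], [GREY_ROI])
        std = [fc.StandardSpec("grey_33", 0.33, GREY_ROI)]
        scales = fc.calibrate_exposure(img, std)
        assert scales[0] == pytest.approx(1.0)

    def test_half_exposure_doubles_scale_and_leaves_reflectance_unchanged(self):
        img_full = _frame_with_standards([0.8, 0.33], [WHITE_ROI, GREY_ROI])
        img_half = img_full.copy_with(channels=0.5 * img_full.channels)
        std = [fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)]
        s_full = fc.calibrate_exposure(img_full, std)
        s_half = fc.calibrate_exposure(img_half, std)
        assert s_half[0] == pytest.approx(2.0 * s_full[0])
        r_full = fc.to_reflectance(img_full, s_full)
        r_half = fc.to_reflectance(img_half, s_half)
        np.testing.assert_allclose(r_half.channels, r_full.channels,
                                   rtol=1e-12)

    def test_multiple_standards_combine_by_inverse_variance(self, rng):
        img = uniform_calibrated(0.1, (96, 96), 1)
        # white patch noisy, grey patch clean: combined scale sits nearer
        # the grey estimate
        img.channels[10:30, 10:30, 0] = 0.8 + rng.normal(0, 0.05, (20, 20))
        img.channels[10:30, 50:70, 0] = 0.33
        white = fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)
        grey = fc.StandardSpec("grey_33", 0.33, GREY_ROI)
        both = fc.calibrate_exposure(img, [white, grey])
        only_grey = fc.calibrate_exposure(img, [grey])
        only_white = fc.calibrate_exposure(img, [white])
        assert (abs(both[0] - only_grey[0])
                < abs(both[0] - only_white[0]))

    def test_clipped_standard_rois_are_excluded(self):
        img = _frame_with_standards([0.9, 0.33], [WHITE_ROI, GREY_ROI])
        img.clipped[10:30, 10:30, :] = True  # white standard overexposed
        white = fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)
        grey = fc.StandardSpec("grey_33", 0.33, GREY_ROI)
        scales = fc.calibrate_exposure(img, [white, grey])
        assert scales[0] == pytest.approx(1.0)  # grey alone sets the scale

    def test_all_standards_unusable_errors(self):
        img = _frame_with_standards([0.9], [WHITE_ROI])
        img.clipped[...] = True
        with pytest.raises(ValueError, match="cannot be calibrated"):
            fc.calibrate_exposure(
                img, [fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)])

    def test_reflectance_scale_input_rejected(self):
        img = uniform_calibrated(0.4).copy_with(scale="reflectance")
        with pytest.raises(ValueError, match="linear"):
            fc.calibrate_exposure(
                img, [fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)])


class TestToReflectance:
    def test_white_standard_is_calibration_fixed_point(self):
        img = _frame_with_standards([0.77], [WHITE_ROI])
        std = [fc.StandardSpec("white_spectralon", 1.0, WHITE_ROI)]
        refl = fc.to_reflectance(img, fc.calibrate_exposure(img, std))
        assert refl.channels[10:30, 10:30, 0].mean() == pytest.approx(1.0)
        assert refl.scale == "reflectance"

    def test_uncertainty_scales_with_channel_factor(self):
        img = _frame_with_standards([0.5], [WHITE_ROI])
        img.uncertainty = np.full_like(img.channels, 0.01)
        scales = np.array([2.0])
        refl = fc.to_reflectance(img, scales)
        np.testing.assert_allclose(refl.uncertainty, 0.02)

    def test_channel_count_mismatch_errors(self):
        img = uniform_calibrated(0.4, n_channels=2)
        with pytest.raises(ValueError, match="per channel"):
            fc.to_reflectance(img, np.array([1.0]))


class TestEndToEnd:
    """Full simulation: render -> linearise -> calibrate -> recover."""

    def _recover(self, profile, illuminant, scene_values, seed=0,
                 noise=None):
        grid = illuminant.grid
        shape = (120, 160)
        rois = {"white": (10, 40, 10, 50), "grey": (10, 40, 60, 100),
                "sample": (60, 110, 20, 140)}
        cov = np.zeros(shape, bool)
        entries = []
        for label, (r0, r1, c0, c1) in rois.items():
            m = np.zeros(shape, bool)
            m[r0:r1, c0:c1] = True
            cov |= m
            entries.append((m, fc.flat_spectrum(scene_values[label], grid)))
        entries.insert(0, (~cov, fc.flat_spectrum(0.1, grid)))
        profile = profile.with_exposure(exposure_for_white(
            profile, illuminant, fc.flat_spectrum(1.0, grid)))
        img = fc.render_scene(entries, profile, illuminant,
                              noise=noise or NoiseSpec.off(), seed=seed)
        luts = [fc.invert_to_lut(profile.transfers[cid], seed=seed)
                for cid in profile.channel_ids]
        cal = fc.linearise_image(img, luts)
        std = [fc.StandardSpec("white_spectralon", 1.0, rois["white"])]
        refl = fc.to_reflectance(cal, fc.calibrate_exposure(cal, std))
        return img, refl, rois

    def test_grey_33_recovers_within_2pct_absolute(self, uv_profile, d65_uv):
        _, refl, rois = self._recover(
            uv_profile, d65_uv,
            {"white": 1.0, "grey": 0.33, "sample": 0.6})
        r0, r1, c0, c1 = rois["grey"]
        got = refl.channels[r0:r1, c0:c1, 0].mean()
        assert got == pytest.approx(0.33, abs=0.02)

    def test_flat_region_recovers_equally_across_channels(self,
                                                          visible_profile,
                                                          d65):
        """A spectrally flat surface is the internal control: every channel
        must report the same reflectance within 2% absolute."""
        _, refl, rois = self._recover(
            visible_profile, d65,
            {"white": 1.0, "grey": 0.33, "sample": 0.55})
        r0, r1, c0, c1 = rois["sample"]
        means = refl.channels[r0:r1, c0:c1, :].mean(axis=(0, 1))
        assert np.ptp(means) < 0.02
        np.testing.assert_allclose(means, 0.55, atol=0.02)

    def test_recovery_invariant_to_global_exposure_rescale(self,
                                                           visible_profile,
                                                           d65):
        grid = d65.grid
        base = visible_profile.with_exposure(exposure_for_white(
            visible_profile, d65, fc.flat_spectrum(1.0, grid)))
        dimmed = base.with_exposure(fc.ExposureSetting(
            tuple(0.5 * s for s in base.exposure.scale_per_channel)))
        shape = (64, 96)
        white_roi, grey_roi = (5, 25, 5, 45), (35, 55, 5, 45)
        cov = np.zeros(shape, bool)
        wmask = np.zeros(shape, bool); wmask[5:25, 5:45] = True
        gmask = np.zeros(shape, bool); gmask[35:55, 5:45] = True
        entries = [(~(wmask | gmask), fc.flat_spectrum(0.2, grid)),
                   (wmask, fc.flat_spectrum(1.0, grid)),
                   (gmask, fc.flat_spectrum(0.45, grid))]
        got = []
        for prof in (base, dimmed):
            img = fc.render_scene(entries, prof, d65,
                                  noise=NoiseSpec.off(), seed=0)
            luts = [fc.invert_to_lut(prof.transfers[cid], n_samples=0)
                    for cid in prof.channel_ids]
            cal = fc.linearise_image(img, luts)
            std = [fc.StandardSpec("white_spectralon", 1.0, white_roi)]
            refl = fc.to_reflectance(cal, fc.calibrate_exposure(cal, std))
            got.append(refl.channels[35:55, 5:45, :].mean(axis=(0, 1)))
        np.testing.assert_allclose(got[0], got[1], atol=0.01)


class TestSaturationCheck:
    def _image(self, sample_level, white_level=230, shape=(64, 64)):
        img = np.full(shape + (3,), 100, dtype=np.uint8)
        img[5:25, 5:25, :] = white_level
        img[35:55, 35:55, :] = 128
        img[35:55, 35:55, 0] = sample_level
        return img

    STD = [fc.StandardSpec("checker_white", 0.95, (5, 25, 5, 25))]
    REGIONS = {"petal": (35, 55, 35, 55)}

    def test_all_regions_below_white_gives_empty_report(self):
        report = fc.saturation_check(self._image(180), self.STD, self.REGIONS)
        assert report["boosted"] == [] and report["clipped"] == []

    def test_red_boost_above_white_flagged_in_red_only(self):
        report = fc.saturation_check(self._image(244), self.STD, self.REGIONS)
        assert [e["channel"] for e in report["boosted"]] == [0]

    def test_clipped_region_reported_as_clipped_not_boosted(self):
        img = self._image(255)
        report = fc.saturation_check(img, self.STD, self.REGIONS)
        assert report["boosted"] == []
        assert [e["channel"] for e in report["clipped"]] == [0]

    def test_requires_white_class_standard(self):
        grey = [fc.StandardSpec("grey_33", 0.33, (5, 25, 5, 25))]
        with pytest.raises(ValueError, match="white"):
            fc.saturation_check(self._image(180), grey, self.REGIONS)
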