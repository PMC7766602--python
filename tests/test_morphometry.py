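import numpy as np
import pytest

from capedema import phantoms as ph
from capedema.clsm_morphometry import (
    ContrastInversionError,
    EmptySegmentationError,
    PapillaSegmentation,
    VesselSegParams,
    brightness_cohort_summary,
    papilla_brightness,
    segment_vessel,
    vessel_size_change,
)
from capedema.imagemodel import CalibratedImage, RoiMask

from conftest import as_image, dense_gaussian


def _disk_image(radius, frame=201, background=200.0, value=0.0):
    c = (frame - 1) / 2
    Y, X = np.meshgrid(np.arange(frame), np.arange(frame), indexing="ij")
    img = np.full((frame, frame), background)
    img[np.hypot(Y - c, X - c) <= radius] = value
    return as_image(img)


class TestSegmentVessel:
    def test_disk_area_recovered(self):
        m = segment_vessel(_disk_image(20), VesselSegParams(smooth_sigma=0.5))
        assert m.area_px == pytest.approx(np.pi * 20**2, rel=0.10)
        assert m.size_px == pytest.approx(20 * np.sqrt(np.pi), rel=0.05)
        assert m.size_px == pytest.approx(np.sqrt(m.area_px))

    def test_all_bright_roi_rejected(self):
        with pytest.raises(EmptySegmentationError):
            segment_vessel(as_image(np.full((50, 50), 7.0)),
                           VesselSegParams(smooth_sigma=2.0))

    def test_relative_threshold_is_scale_invariant(self):
        params = VesselSegParams(smooth_sigma=1.0)
        img = _disk_image(15)
        half = as_image(img.pixels * 0.5)
        m1, m2 = segment_vessel(img, params), segment_vessel(half, params)
        np.testing.assert_array_equal(m1.mask.mask, m2.mask.mask)

    def test_size_monotone_in_radius(self):
        params = VesselSegParams(smooth_sigma=0.5)
        sizes = [segment_vessel(_disk_image(r), params).size_px
                 for r in range(8, 41, 4)]
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_largest_component_selected(self):
        img = _disk_image(15)
        px = img.pixels.copy()
        px[2:6, 2:6] = 0.0  # small stray dark corner
        m = segment_vessel(as_image(px), VesselSegParams(smooth_sigma=1.0))
        # mask is the central disk, not the corner
        assert m.mask.mask[100, 100]
        assert not m.mask.mask[3, 3]
        assert m.component_policy_used == "largest_component"

    def test_smooth_um_converts_through_pitch(self):
        img = _disk_image(20)
        via_px = segment_vessel(img, VesselSegParams(smooth_sigma=2.0))
        via_um = segment_vessel(img, VesselSegParams(smooth_sigma=None, smooth_um=2.0))
        np.testing.assert_array_equal(via_px.mask.mask, via_um.mask.mask)

    def test_brute_force_equivalence_on_small_phantom(self, rng):
        """Smoothing + relative threshold agrees with an explicit dense
        convolution re-implementation, up to one boundary pixel layer."""
        frame = 64
        img = _disk_image(12, frame=frame)
        params = VesselSegParams(smooth_sigma=1.5)
        m = segment_vessel(img, params)
        smoothed = dense_gaussian(img.pixels, 1.5)
        ref = smoothed < params.threshold_frac * smoothed.max()
        disagree = m.mask.mask ^ ref
        from scipy import ndimage
        interior = ndimage.binary_erosion(ref, np.ones((3, 3)))
        assert not (disagree & interior).any()


class TestVesselSizeChange:
    def test_ten_percent_increase(self):
        before = [_fake_measurement(10.0)] * 3
        after = [_fake_measurement(11.0)] * 3
        assert vessel_size_change(before, after) == pytest.approx(10.0)

    def test_identical_lists_zero_change(self):
        ms = [_fake_measurement(7.0)] * 4
        assert vessel_size_change(ms, ms) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            vessel_size_change([], [_fake_measurement(1.0)])

    def test_occlusion_dataset_recovery(self):
        ds = ph.make_effect_dataset(
            ph.EffectModel("occlusion_dilation", 1.10, n_pairs=20, seed=77))
        p = VesselSegParams(smooth_sigma=2.0)
        before = [segment_vessel(pair["before"], p) for pair in ds["pairs"]]
        after = [segment_vessel(pair["after"], p) for pair in ds["pairs"]]
        assert vessel_size_change(before, after) == pytest.approx(10.0, abs=3.0)


def _fake_measurement(size_px):
    class _M:
        pass
    m = _M()
    m.size_px = size_px
    m.size_um = size_px
    return m


class TestPapillaBrightness:
    def _exact_phantom(self, papilla_level=0.25):
        spec = ph.PapillaPhantomSpec(intensities=(0.0, papilla_level, 1.0, 0.5))
        return ph.make_papilla_phantom(spec)

    def test_closed_form_value(self):
        img, seg = self._exact_phantom()
        assert papilla_brightness(img, seg).value == pytest.approx(25.0, abs=1e-9)

    def test_gain_invariance(self):
        img, seg = self._exact_phantom()
        doubled = CalibratedImage(2.0 * img.pixels, 1.0)
        assert papilla_brightness(doubled, seg).value == pytest.approx(
            papilla_brightness(img, seg).value, abs=1e-12)

    def test_offset_covariance_matches_formula(self):
        img, seg = self._exact_phantom()
        off = CalibratedImage(img.pixels + 0.1, 1.0)
        # ring-lumen difference is offset-free; papilla mean shifts by the offset
        expect = 100.0 * (0.25 + 0.1) / (1.0 - 0.0)
        assert papilla_brightness(off, seg).value == pytest.approx(expect, abs=1e-9)

    def test_papilla_drop_gives_proportional_decrease(self):
        img1, seg = self._exact_phantom(0.50)
        img2, _ = self._exact_phantom(0.40)
        v1 = papilla_brightness(img1, seg).value
        v2 = papilla_brightness(img2, seg).value
        assert (v1, v2) == (pytest.approx(50.0), pytest.approx(40.0))
        assert (v1 - v2) / v1 == pytest.approx(0.20)

    def test_contrast_inversion_rejected(self):
        img, seg = self._exact_phantom()
        inverted = CalibratedImage(1.0 - img.pixels, 1.0)
        with pytest.raises(ContrastInversionError):
            papilla_brightness(inverted, seg)

    def test_masks_must_be_disjoint(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True
        with pytest.raises(ValueError):
            PapillaSegmentation(RoiMask("papilla", m), RoiMask("ring", m),
                                RoiMask("lumen", ~m))


class TestCohortSummary:
    def _pb(self, v):
        from capedema.clsm_morphometry import PapillaBrightness
        return PapillaBrightness(v, v / 100, 1.0, 0.0)

    def test_two_group_percent_change(self):
        meas = [self._pb(25.0)] * 3 + [self._pb(20.0)] * 3
        labels = ["before"] * 3 + ["after"] * 3
        s = brightness_cohort_summary(meas, labels)
        assert s["percent_change"] == pytest.approx(-20.0)
        assert s["warnings"]  # n=3 < 10 recommended

    def test_single_group_summary_without_change(self):
        s = brightness_cohort_summary([self._pb(25.0)] * 4, ["only"] * 4)
        assert s["percent_change"] is None
        assert any("only" in w for w in s["warnings"])

    def test_hyporefractivity_dataset_recovery(self):
        ds = ph.make_effect_dataset(
            ph.EffectModel("histamine_hyporefractivity", 0.20, n_pairs=12, seed=9),
            ph.PapillaPhantomSpec(noise_sigma=0.02))
        meas, labels = [], []
        for pair in ds["pairs"]:
            meas.append(papilla_brightness(pair["before"], pair["before_truth"]))
            labels.append("before")
            meas.append(papilla_brightness(pair["after"], pair["after_truth"]))
            labels.append("after")
        s = brightness_cohort_summary(meas, labels)
        assert s["percent_change"] == pytest.approx(-20.0, abs=3.0)
        assert not s["warnings"]
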