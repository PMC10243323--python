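"""MR image-quality metrics: formulas, worksheet parity, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainmrqa.core import MaskROI, PlanarImage, ValidationError
from brainmrqa.qa import (
    AcrReport,
    ComputationError,
    ROIStats,
    full_lcod_score,
    geometric_lengths,
    ghosting_ratio,
    low_contrast_count,
    percent_uniformity,
    piu,
    roi_stats,
    snr,
)
from brainmrqa.synth import make_low_contrast_slice, make_uniform_phantom


def _stats(mean=0.0, sd=1.0, mx=None, mn=None, count=10):
    mx = mean if mx is None else mx
    mn = mean if mn is None else mn
    return ROIStats(mean=mean, sd=sd, max=mx, min=mn, count=count)


class TestRoiStats:
    def test_constant_region(self):
        img = PlanarImage(np.full((20, 20), 100.0), (1.0, 1.0))
        st_ = roi_stats(img, MaskROI(np.ones((20, 20), dtype=bool)))
        assert (st_.mean, st_.sd, st_.max, st_.min) == (100.0, 0.0, 100.0, 100.0)

    def test_hand_arithmetic_three_values(self):
        img = PlanarImage(np.array([[1.0, 2.0, 3.0]]), (1.0, 1.0))
        st_ = roi_stats(img, MaskROI(np.ones((1, 3), dtype=bool)))
        assert st_.mean == 2.0 and st_.sd == 1.0  # n-1 denominator

    def test_noise_sd_estimate_on_large_roi(self):
        rng = np.random.default_rng(0)
        img = PlanarImage(rng.normal(300.0, 5.0, (128, 128)), (1.0, 1.0))
        st_ = roi_stats(img, MaskROI(np.ones((128, 128), dtype=bool)))
        assert abs(st_.sd - 5.0) <= 0.5

    def test_area_in_cm2(self):
        img = PlanarImage(np.zeros((100, 100)), (1.3, 1.3))
        st_ = roi_stats(img, MaskROI(np.ones((100, 100), dtype=bool)))
        assert np.isclose(st_.roi_area_cm2, 100 * 100 * 1.69 / 100.0)

    def test_empty_roi_rejected(self):
        img = PlanarImage(np.zeros((4, 4)), (1.0, 1.0))
        with pytest.raises(ValidationError):
            roi_stats(img, MaskROI(np.zeros((4, 4), dtype=bool)))


class TestSnr:
    def test_rayleigh_factor_cancels(self):
        assert snr(_stats(mean=100.0), _stats(sd=0.66)) == pytest.approx(100.0)

    def test_zero_signal(self):
        assert snr(_stats(mean=0.0), _stats(sd=2.0)) == 0.0

    def test_zero_noise_rejected(self):
        with pytest.raises(ComputationError):
            snr(_stats(mean=10.0), _stats(sd=0.0))

    def test_direct_formula_example(self):
        # signal mean 200 against a noise ROI with SD 5 → 200 × 0.66 / 5
        assert snr(_stats(mean=200.0), _stats(sd=5.0)) == pytest.approx(26.4)

    def test_magnitude_background_recovers_true_snr(self):
        """On magnitude images the 0.66 factor turns the Rayleigh
        background SD into the underlying Gaussian sigma, so the formula
        approximates mean/sigma."""
        rng = np.random.default_rng(1)
        sigma, mean_sig = 5.0, 200.0
        bg = np.hypot(rng.normal(0, sigma, 20000), rng.normal(0, sigma, 20000))
        noise = _stats(sd=float(bg.std(ddof=1)))
        value = snr(_stats(mean=mean_sig), noise)
        assert abs(value - mean_sig / sigma) / (mean_sig / sigma) <= 0.05

    def test_linearity_in_signal_and_inverse_in_noise(self):
        base = snr(_stats(mean=100.0), _stats(sd=2.0))
        assert snr(_stats(mean=300.0), _stats(sd=2.0)) == pytest.approx(3 * base)
        assert snr(_stats(mean=100.0), _stats(sd=4.0)) == pytest.approx(base / 2)


class TestUniformity:
    def test_extremes(self):
        assert percent_uniformity(_stats(mean=7, mx=7.0, mn=7.0)) == 100.0
        assert percent_uniformity(_stats(mean=4, mx=8.0, mn=0.0)) == 0.0

    def test_direct_evaluation(self):
        st_ = _stats(mean=730.0, mx=759.16, mn=702.75)
        assert percent_uniformity(st_) == pytest.approx(96.14, abs=0.005)

    @pytest.mark.parametrize("low,high,expected", [
        (702.75, 759.16, 96.1),   # head and neck coil worksheet
        (741.27, 757.2, 98.9),    # torso coil
        (2193.23, 2517.25, 93.1),  # high-resolution brain coil
    ])
    def test_piu_worksheet_parity(self, low, high, expected):
        assert piu(low, high) == expected

    def test_piu_agrees_with_percent_uniformity(self):
        st_ = _stats(mean=1000.0, mx=1100.0, mn=900.0)
        assert piu(900.0, 1100.0) == pytest.approx(percent_uniformity(st_), abs=0.05)

    def test_piu_validation(self):
        with pytest.raises(ValidationError):
            piu(10.0, 5.0)
        with pytest.raises(ValidationError):
            piu(-1.0, 5.0)
        assert piu(5.0, 5.0) == 100.0


class TestGhosting:
    @pytest.mark.parametrize("rois,expected", [
        ((20.6, 21.2, 33.5, 40.9, 733.2), 0.022),  # head and neck coil
        ((24.7, 23.3, 36.9, 35.0, 749.6), 0.016),  # torso coil
        ((26.4, 26.1, 24.0, 21.0, 2295.3), 0.002),  # brain coil
    ])
    def test_worksheet_parity(self, rois, expected):
        assert ghosting_ratio(*rois) == expected

    def test_symmetric_field_is_zero(self):
        assert ghosting_ratio(10.0, 12.0, 11.0, 11.0, 500.0) == 0.0

    def test_nonpositive_large_roi_rejected(self):
        with pytest.raises(ValidationError):
            ghosting_ratio(1, 1, 1, 1, 0.0)

    def test_synthetic_ghost_increases_ratio_monotonically(self):
        ratios = []
        for g in (0.0, 0.01, 0.02, 0.04):
            img, mask = make_uniform_phantom(ghost_fraction=g, signal=1000.0)
            px, n = img.pixels, img.shape[0]
            top = px[5:25, n // 2 - 10 : n // 2 + 10].mean()
            bottom = px[-25:-5, n // 2 - 10 : n // 2 + 10].mean()
            left = px[n // 2 - 10 : n // 2 + 10, 5:25].mean()
            right = px[n // 2 - 10 : n // 2 + 10, -25:-5].mean()
            large = px[mask.mask].mean()
            ratios.append(ghosting_ratio(top, bottom, left, right, large))
        assert ratios == sorted(ratios) and ratios[-1] > ratios[0]


class TestLowContrast:
    def test_saturated_contrast_counts_all_spokes(self):
        img, tpl = make_low_contrast_slice([50.0] * 10, noise_sigma=5.0, rng=0)
        assert low_contrast_count(img, tpl) == 10

    def test_partial_contrast_counts_visible_spokes(self):
        img, tpl = make_low_contrast_slice([50.0] * 7 + [0.0] * 3,
                                           noise_sigma=5.0, rng=0)
        assert low_contrast_count(img, tpl) == 7

    def test_blank_disk_counts_zero(self):
        img, tpl = make_low_contrast_slice([0.0] * 10, noise_sigma=5.0, rng=0)
        assert low_contrast_count(img, tpl) == 0

    def test_count_monotone_in_cnr(self):
        sigma = 5.0
        counts = []
        for cnr in (0.0, 1.0, 2.0, 5.0, 10.0):
            img, tpl = make_low_contrast_slice([cnr * sigma] * 10,
                                               noise_sigma=sigma, rng=3)
            counts.append(low_contrast_count(img, tpl))
        assert counts == sorted(counts)
        assert counts[0] == 0 and counts[-1] == 10

    @pytest.mark.parametrize("counts,expected", [
        ((1, 8, 9, 10), 28),   # head and neck coil, slices 8–11
        ((3, 8, 9, 10), 30),   # torso coil
        ((8, 9, 10, 10), 37),  # brain coil
        ((0, 0, 0, 0), 0),
    ])
    def test_full_score_sums(self, counts, expected):
        assert full_lcod_score(counts) == expected

    def test_full_score_validation(self):
        with pytest.raises(ValidationError):
            full_lcod_score((1, 2, 3))
        with pytest.raises(ValidationError):
            full_lcod_score((1, 2, 3, 11))


class TestGeometricLengths:
    def test_disk_diameter_at_two_spacings(self):
        for spacing, expected, tol in ((1.0, 190.0, 0.5), (0.5, 95.0, 0.25)):
            img, _ = make_uniform_phantom(shape=(256, 256), spacing_mm=spacing,
                                          diameter_mm=expected, signal=800.0)
            lengths = geometric_lengths(img)
            assert abs(lengths["row"] - expected) <= tol
            assert abs(lengths["col"] - expected) <= tol

    def test_ellipse_axes(self):
        img, _ = make_uniform_phantom(shape=(220, 220), spacing_mm=1.0,
                                      diameter_mm=(190.0, 148.0), signal=800.0)
        lengths = geometric_lengths(img)
        assert abs(lengths["row"] - 190.0) <= 0.5
        assert abs(lengths["col"] - 148.0) <= 0.5

    def test_flat_image_raises(self):
        from brainmrqa.qa import DetectionEdgeError

        with pytest.raises(DetectionEdgeError):
            geometric_lengths(PlanarImage(np.ones((32, 32)), (1.0, 1.0)))


class TestAcrReport:
    def test_report_collects_worksheet_values(self):
        rep = AcrReport(
            lcod_counts={8: 8, 9: 9, 10: 10, 11: 10},
            uniformity_low=2193.23,
            uniformity_high=2517.25,
            ghosting_rois=dict(top=26.4, bottom=26.1, left=24.0, right=21.0,
                               large_roi=2295.3),
        )
        d = rep.to_dict()
        assert d["lcod_full"] == 37
        assert d["uniformity"]["piu_display"] == "93.1"
        assert d["ghosting"]["ratio_display"] == "0.002"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            AcrReport(lcod_counts={8: 12})


@settings(max_examples=30, derandomize=True)
@given(low=st.floats(1.0, 5000.0), high=st.floats(1.0, 5000.0))
def test_piu_bounded_between_0_and_100(low, high):
    lo, hi = sorted((low, high))
    assert 0.0 <= piu(lo, hi) <= 100.0
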