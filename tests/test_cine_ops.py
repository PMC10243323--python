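"""Unit tests for the individual cine-pipeline stages."""

import numpy as np
import pytest
from scipy import ndimage

from brainmrqa.core import (
    MaskROI,
    PlanarCineSequence,
    PlanarImage,
    ValidationError,
)
from brainmrqa.cine import (
    DetectionError,
    FillError,
    SimilarityError,
    TrackingConfig,
    build_registration_roi,
    crop_system_boundary,
    detect_contours,
    detect_crosslines,
    fill_contour,
    gate_check,
    inpaint_overlay,
    pearson_similarity,
)
from brainmrqa.synth import (
    CrosslineSpec,
    make_cine,
    make_head_slice,
    static_schedule,
)


def _seq_of(arrays, spacing=(1.0, 1.0)):
    return PlanarCineSequence(
        tuple(PlanarImage(a, spacing) for a in arrays), 1.0
    )


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestCrop:
    def test_uniform_margin_geometry(self):
        seq = _seq_of([np.random.default_rng(0).random((200, 200))] * 2)
        out = crop_system_boundary(seq, 10)
        assert out.frames[0].shape == (180, 180)
        assert out.frames[0].spacing_mm == seq.frames[0].spacing_mm

    def test_zero_margin_is_identity(self):
        seq = _seq_of([np.random.default_rng(0).random((32, 32))])
        out = crop_system_boundary(seq, 0)
        assert out is seq

    def test_auto_detects_generator_border_exactly(self, head_spec_noisy, center160):
        seq, _ = make_cine(head_spec_noisy, schedule=static_schedule(2, center160),
                           seed=0, border_px=7)
        out = crop_system_boundary(seq, "auto")
        assert out.frames[0].shape == (160, 160)

    def test_overfull_crop_rejected(self):
        seq = _seq_of([np.random.default_rng(0).random((20, 20))])
        with pytest.raises(ValidationError):
            crop_system_boundary(seq, 10)


class TestContours:
    def test_disk_outline_and_centroid(self):
        img = PlanarImage(np.where(_disk((64, 64), (30.0, 34.0), 20), 200.0, 10.0),
                          (1.0, 1.0))
        cs = detect_contours(img)
        rr, cc = np.nonzero(cs.target_outline.mask)
        dist = np.hypot(rr - 30.0, cc - 34.0)
        assert dist.min() >= 19.0 and dist.max() <= 21.0
        assert abs(cs.rotation_center[0] - 30.0) <= 0.5
        assert abs(cs.rotation_center[1] - 34.0) <= 0.5

    def test_blank_frame_raises_detection_error(self):
        with pytest.raises(DetectionError):
            detect_contours(PlanarImage(np.full((32, 32), 7.0), (1.0, 1.0)))

    def test_largest_of_two_disks_selected(self):
        px = np.full((96, 96), 5.0)
        px[_disk((96, 96), (30, 30), 18)] = 200.0
        px[_disk((96, 96), (70, 70), 8)] = 200.0
        cs = detect_contours(PlanarImage(px, (1.0, 1.0)))
        assert abs(cs.rotation_center[0] - 30) < 1 and abs(cs.rotation_center[1] - 30) < 1

    def test_boundary_is_target_expanded_by_gating_margin(self):
        img = PlanarImage(np.where(_disk((64, 64), (32, 32), 15), 200.0, 10.0),
                          (1.0, 1.0))
        cs = detect_contours(img, TrackingConfig(gating_margin_mm=3.0))
        assert cs.boundary_filled.count > cs.target_filled.count
        assert not np.any(cs.target_filled.mask & ~cs.boundary_filled.mask)


class TestFillContour:
    def test_circle_outline_fills_to_analytic_area(self):
        shape, c, r = (64, 64), (31.0, 31.0), 20.0
        disk = _disk(shape, c, r)
        outline = disk & ~ndimage.binary_erosion(disk)
        filled, center = fill_contour(MaskROI(outline, "circle"))
        assert abs(filled.count - np.pi * r**2) <= 0.02 * np.pi * r**2
        assert abs(center[0] - c[0]) <= 0.5 and abs(center[1] - c[1]) <= 0.5

    def test_idempotent_on_filled_mask(self):
        disk = _disk((64, 64), (31, 31), 15)
        filled, _ = fill_contour(MaskROI(disk))
        assert np.array_equal(filled.mask, disk)

    def test_one_pixel_gap_closed_by_dilation(self):
        disk = _disk((64, 64), (31, 31), 18)
        outline = disk & ~ndimage.binary_erosion(disk)
        outline[31, 49] = False  # puncture the curve
        filled, _ = fill_contour(MaskROI(outline), dilation_radius=2)
        assert filled.count > 0.9 * np.pi * 18**2

    def test_open_arc_raises_fill_error(self):
        arc = np.zeros((64, 64), dtype=bool)
        arc[10, 10:40] = True  # a line encloses nothing
        with pytest.raises(FillError):
            fill_contour(MaskROI(arc))


class TestInpaint:
    def test_constant_field_restored_exactly(self):
        img = PlanarImage(np.full((32, 32), 100.0), (1.0, 1.0))
        overlay = MaskROI(_disk((32, 32), (16, 16), 6))
        out = inpaint_overlay(img, overlay)
        assert np.allclose(out.pixels, 100.0)

    def test_linear_ramp_through_thin_line(self):
        ramp = np.tile(np.arange(48, dtype=float), (48, 1))
        overlay = np.zeros((48, 48), dtype=bool)
        overlay[:, 20] = True
        out = inpaint_overlay(PlanarImage(ramp, (1.0, 1.0)), MaskROI(overlay))
        assert np.abs(out.pixels[:, 20] - 20.0).max() <= 1.0
        # untouched elsewhere
        assert np.array_equal(out.pixels[:, :20], ramp[:, :20])

    def test_empty_overlay_is_identity(self):
        img = PlanarImage(np.random.default_rng(0).random((16, 16)), (1.0, 1.0))
        out = inpaint_overlay(img, MaskROI(np.zeros((16, 16), dtype=bool)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_full_overlay_rejected(self):
        img = PlanarImage(np.ones((8, 8)), (1.0, 1.0))
        with pytest.raises(ValidationError):
            inpaint_overlay(img, MaskROI(np.ones((8, 8), dtype=bool)))


class TestCrosslines:
    def test_uniform_frame_flags_nothing(self):
        art = detect_crosslines(PlanarImage(np.full((40, 40), 50.0), (1, 1)), "row")
        assert art.indices == ()

    def test_raised_row_flagged_exactly(self, head_spec_noisy, center160):
        seq, _ = make_cine(head_spec_noisy, schedule=static_schedule(2, center160),
                           crosslines=[CrosslineSpec("row", 37, 1.5)], seed=0)
        cs = detect_contours(seq.frames[0])
        exclude = MaskROI(ndimage.binary_dilation(cs.target_filled.mask, iterations=6))
        art = detect_crosslines(seq.frames[0], "row", threshold_k=5.0, exclude=exclude)
        assert art.indices == (37,)
        assert all(s > 5.0 for s in art.strengths)

    def test_two_saturated_columns_no_false_positives(self):
        # noise-only frames: 50 realizations, zero spurious detections
        rng = np.random.default_rng(11)
        for _ in range(50):
            px = np.abs(rng.normal(100.0, 5.0, (60, 60)))
            clean = detect_crosslines(PlanarImage(px, (1, 1)), "col", 5.0)
            assert clean.indices == ()
            px2 = px.copy()
            px2[:, 12] *= 3.0
            px2[:, 41] *= 3.0
            art = detect_crosslines(PlanarImage(px2, (1, 1)), "col", 5.0)
            assert art.indices == (12, 41)

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValidationError):
            detect_crosslines(PlanarImage(np.ones((3, 10)), (1, 1)), "row")


class TestRegistrationRoi:
    def test_annulus_of_configured_width(self):
        disk = _disk((64, 64), (31, 31), 15)
        roi = build_registration_roi(MaskROI(disk), None, outer_mm=3.0, inner_mm=3.0,
                                     spacing_mm=(1.0, 1.0))
        rr, cc = np.nonzero(roi.mask)
        dist = np.hypot(rr - 31, cc - 31)
        assert dist.min() >= 11.0 and dist.max() <= 19.5
        assert not np.any(roi.mask & ndimage.binary_erosion(disk, iterations=3))

    def test_crossline_rows_removed_from_roi(self):
        disk = _disk((64, 64), (31, 31), 15)
        from brainmrqa.cine import CrosslineArtifact

        art = CrosslineArtifact("row", (31,), (9.9,))
        roi = build_registration_roi(MaskROI(disk), art, spacing_mm=(1.0, 1.0))
        assert not roi.mask[31].any()

    def test_fully_excluded_roi_rejected(self):
        from brainmrqa.cine import CrosslineArtifact

        disk = _disk((32, 32), (15, 15), 6)
        art = CrosslineArtifact("row", tuple(range(32)), (9.0,) * 32)
        with pytest.raises(ValidationError):
            build_registration_roi(MaskROI(disk), art, spacing_mm=(1.0, 1.0))


class TestPearson:
    def test_identity_and_sign_flip(self):
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert pearson_similarity(v, v) == 1.0
        assert pearson_similarity(v, -v) == -1.0

    def test_hand_computed_value(self):
        assert np.isclose(pearson_similarity([1, 2, 3], [1, 3, 2]), 0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(SimilarityError):
            pearson_similarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pearson_similarity([1, 2], [1, 2, 3])


class TestGateCheck:
    def test_target_inside_boundary_beam_on(self):
        target = MaskROI(_disk((64, 64), (32, 32), 10))
        boundary = MaskROI(_disk((64, 64), (32, 32), 13))
        d = gate_check(target, boundary)
        assert d.beam_on and d.excursion_fraction == 0.0

    def test_shift_beyond_expansion_beam_off(self):
        # 3 mm expansion at 1 mm pixels; 5 px shift pushes the target out
        target = MaskROI(_disk((64, 64), (32, 37), 10))
        boundary = MaskROI(_disk((64, 64), (32, 32), 13))
        d = gate_check(target, boundary)
        assert not d.beam_on and d.excursion_fraction > 0.0

    def test_target_equal_boundary_is_on_at_limit(self):
        m = MaskROI(_disk((64, 64), (32, 32), 10))
        d = gate_check(m, m)
        assert d.beam_on and d.excursion_fraction == 0.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValidationError):
            gate_check(MaskROI(np.zeros((8, 8), dtype=bool)),
                       MaskROI(np.ones((8, 8), dtype=bool)))
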