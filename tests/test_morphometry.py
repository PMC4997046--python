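"""Segmentation, axis estimation, half-spindle measurement and topology."""

import numpy as np
import pytest

from conftest import run_pipeline

from spindlemetrics import (
    ImageStack,
    SpindleGroundTruth,
    detect_topology,
    estimate_axis_and_plate,
    generate_spindle_stack,
    measure_half_spindle,
    segment_channel,
    segment_stack,
)
from spindlemetrics.errors import (
    AnisotropyError,
    DegenerateInputError,
    MissingPoleError,
)
from spindlemetrics.morphometry import SegmentationResult, _fwhm
from spindlemetrics.stack import DNA, TUBULIN
from spindlemetrics.synthetic import Optics


def _stack3d(tub, dna=None, voxel_size=(1.0, 0.2, 0.2)):
    dna = dna if dna is not None else np.zeros_like(tub)
    return ImageStack({TUBULIN: tub, DNA: dna}, voxel_size)


class TestSegmentation:
    def test_all_zero_image_is_degenerate(self):
        stack = _stack3d(np.zeros((8, 16, 16)))
        with pytest.raises(DegenerateInputError):
            segment_channel(stack, TUBULIN)

    def test_two_level_image_segments_exactly(self):
        img = np.zeros((10, 20, 20))
        img[3:7, 5:15, 5:15] = 100.0
        seg = segment_channel(_stack3d(img), TUBULIN)
        np.testing.assert_array_equal(seg.mask, img > 0)
        assert 0 < seg.threshold < 100

    def test_small_objects_removed(self):
        img = np.zeros((10, 20, 20))
        img[3:7, 5:15, 5:15] = 100.0
        img[0, 0, 0] = 100.0  # single speck, below the 27-voxel floor
        seg = segment_channel(_stack3d(img), TUBULIN)
        assert not seg.mask[0, 0, 0]
        assert seg.mask[5, 10, 10]

    def test_mask_covers_ground_truth_fibers(self, noiseless_cone):
        stack, _, masks = noiseless_cone
        seg = segment_channel(stack, TUBULIN)
        cover = (seg.mask & masks.tubulin).sum() / masks.tubulin.sum()
        assert cover >= 0.90


class TestAxisEstimation:
    def test_axis_recovered_along_x(self, noisy_phantom):
        stack, truth, _ = noisy_phantom
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        frame = estimate_axis_and_plate(stack, seg)
        assert abs(frame.axis @ truth.plate_normal) >= 0.99
        assert np.linalg.norm(frame.plate_center - truth.plate_center) < 0.5

    def test_axis_recovered_after_rotation(self):
        angle = np.deg2rad(20)
        rot_axis = np.array([0.0, np.sin(angle), np.cos(angle)])
        truth = SpindleGroundTruth.bipolar(axis=rot_axis, divergence=0.3,
                                           seed=31)
        stack, _ = generate_spindle_stack(truth, Optics.noiseless())
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        frame = estimate_axis_and_plate(stack, seg)
        misalignment = np.degrees(np.arccos(min(1.0, abs(frame.axis @ rot_axis))))
        assert misalignment < 2.0

    def test_uniform_ball_has_no_axis(self):
        shape, vs = (24, 120, 120), (1.0, 0.2, 0.2)
        zz, yy, xx = np.meshgrid(*(np.arange(n) * d for n, d in zip(shape, vs)),
                                 indexing="ij")
        c = ((np.array(shape) - 1) * np.array(vs)) / 2
        ball = (((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
                <= 8.0 ** 2).astype(float) * 100
        stack = _stack3d(ball, dna=ball, voxel_size=vs)
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        with pytest.raises(AnisotropyError):
            estimate_axis_and_plate(stack, seg)


class TestHalfSpindleMeasurement:
    def test_cylinder_limit_focus_ratio_near_one(self, noiseless_cylinder):
        stack, _, _ = noiseless_cylinder
        _, _, ms = run_pipeline(stack)
        for m in ms:
            assert m.focus_ratio == pytest.approx(1.0, abs=0.05)

    def test_cone_matches_linear_closed_form(self, noiseless_cone):
        # an ideal cone has width W(f) = (1 - f) * W_C, so f=0.75 gives 0.25
        stack, _, _ = noiseless_cone
        _, _, ms = run_pipeline(stack)
        for m in ms:
            assert m.focus_ratio == pytest.approx(0.25, abs=0.05)

    def test_plate_width_and_length_recovered(self, noisy_phantom):
        stack, truth, _ = noisy_phantom
        _, _, ms = run_pipeline(stack)
        tol = max(1.0, 0.6)  # coarsest voxel pitch vs axial PSF sigma, um
        for m in ms:
            assert m.w_c == pytest.approx(truth.plate_width_true, abs=tol)
            assert m.length == pytest.approx(truth.half_length_true, abs=tol)

    def test_ratio_identity_and_pole_on_axis(self, noisy_phantom):
        stack, _, _ = noisy_phantom
        _, frame, ms = run_pipeline(stack)
        for m in ms:
            assert m.focus_ratio == m.w_s / m.w_c
            expected_pole = (m.plate_center
                             + (1 if m.half_spindle_id == 1 else -1)
                             * m.length * m.axis)
            assert np.linalg.norm(m.pole_point - expected_pole) < 1e-9

    def test_missing_pole_side_raises(self, noisy_phantom):
        stack, _, _ = noisy_phantom
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        frame = estimate_axis_and_plate(stack, seg)
        # plate centre pushed beyond the pole leaves side 1 empty
        far_center = frame.plate_center + 30.0 * frame.axis
        with pytest.raises(MissingPoleError):
            measure_half_spindle(stack, seg, frame.axis, far_center,
                                 half_spindle_id=1)

    def test_focus_ratio_monotone_in_divergence(self):
        ratios = []
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            truth = SpindleGroundTruth.bipolar(divergence=d, seed=23)
            stack, _ = generate_spindle_stack(truth, Optics.noiseless())
            _, _, ms = run_pipeline(stack)
            ratios.append(np.mean([m.focus_ratio for m in ms]))
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_scale_equivariance(self):
        def measure(plate_width, half_length, vs, psf, plate_thickness):
            truth = SpindleGroundTruth.bipolar(
                plate_width=plate_width, half_length=half_length,
                divergence=0.3, seed=31, voxel_size=vs)
            stack, _ = generate_spindle_stack(
                truth, Optics.noiseless(psf_sigma=psf), voxel_size=vs,
                plate_thickness=plate_thickness)
            _, _, ms = run_pipeline(stack)
            return ms[0]

        base = measure(10.0, 12.0, (1.0, 0.2, 0.2), (0.6, 0.25, 0.25), 2.0)
        half = measure(5.0, 6.0, (0.5, 0.1, 0.1), (0.3, 0.125, 0.125), 1.0)
        assert half.w_c == pytest.approx(base.w_c / 2, rel=0.02)
        assert half.length == pytest.approx(base.length / 2, rel=0.02)
        assert half.w_s == pytest.approx(base.w_s / 2, rel=0.02)
        assert half.focus_ratio == pytest.approx(base.focus_ratio, rel=0.02)

    def test_rotation_invariance_of_measurements(self):
        def measure(axis):
            truth = SpindleGroundTruth.bipolar(axis=axis, divergence=0.3,
                                               seed=31)
            stack, _ = generate_spindle_stack(truth, Optics.noiseless())
            _, _, ms = run_pipeline(stack)
            return ms[0]

        angle = np.deg2rad(20)
        base = measure((0.0, 0.0, 1.0))
        rot = measure((0.0, np.sin(angle), np.cos(angle)))
        for attr in ("w_c", "length", "w_s", "focus_ratio"):
            assert getattr(rot, attr) == pytest.approx(
                getattr(base, attr), rel=0.05)

    def test_fwhm_matches_brute_force_scan(self, noiseless_cylinder):
        # oracle equivalence: the measurement-path FWHM agrees with a naive
        # half-max crossing count on the same profile within one lateral voxel
        stack, _, _ = noiseless_cylinder
        img = stack.channel(TUBULIN)
        prof = img[9, :, 120].astype(float)
        s = np.arange(len(prof)) * stack.voxel_size[1]
        plateau = np.median(prof[prof >= 0.75 * prof.max()])
        above = np.flatnonzero(prof > plateau / 2)
        brute = s[above[-1]] - s[above[0]]
        assert _fwhm(s, prof) == pytest.approx(brute, abs=stack.voxel_size[1])


class TestTopology:
    def test_single_bipolar_spindle(self, noisy_phantom):
        stack, _, _ = noisy_phantom
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        topo = detect_topology(seg, min_gap=2.0)
        assert topo.n_spindle_components == 1
        assert topo.n_poles == [2]

    def test_two_separated_spindles(self):
        truth = SpindleGroundTruth.multi_spindle(n_spindles=2, gap=5.0, seed=7)
        stack, _ = generate_spindle_stack(truth, Optics())
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        topo = detect_topology(seg, min_gap=2.0)
        assert topo.n_spindle_components == 2

    def test_tripolar_spindle(self):
        truth = SpindleGroundTruth.tripolar(seed=7)
        stack, _ = generate_spindle_stack(truth, Optics())
        seg = segment_stack(stack, channels=(TUBULIN, DNA))
        topo = detect_topology(seg, min_gap=2.0)
        assert topo.n_spindle_components == 1
        assert topo.n_poles == [3]

    def test_empty_mask_yields_zero_components(self):
        seg = SegmentationResult(
            channel=TUBULIN, mask=np.zeros((5, 8, 8), dtype=bool),
            method="otsu", threshold=1.0, voxel_size=(1.0, 0.2, 0.2))
        topo = detect_topology(seg)
        assert topo.n_spindle_components == 0
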