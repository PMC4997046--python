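import numpy as np
import pytest

from spindlemetrics import (
    SpindleGroundTruth,
    estimate_axis_and_plate,
    generate_spindle_stack,
    measure_half_spindle,
    segment_stack,
)
from spindlemetrics.stack import DNA, TUBULIN
from spindlemetrics.synthetic import Optics


def run_pipeline(stack, fraction=0.75):
    """Segment, estimate the spindle frame, measure both half-spindles."""
    seg = segment_stack(stack, channels=(TUBULIN, DNA))
    frame = estimate_axis_and_plate(stack, seg)
    measurements = [
        measure_half_spindle(stack, seg, frame.axis, frame.plate_center,
                             fraction=fraction, half_spindle_id=h)
        for h in (1, 2)
    ]
    return seg, frame, measurements


def mean_focus_ratio(stack, fraction=0.75):
    _, _, ms = run_pipeline(stack, fraction)
    return float(np.mean([m.focus_ratio for m in ms]))


@pytest.fixture(scope="session")
def noiseless_cylinder():
    """Non-converging spindle phantom: fibers stay a uniform cylinder."""
    truth = SpindleGroundTruth.bipolar(divergence=1.0, seed=11)
    stack, truth, masks = generate_spindle_stack(
        truth, Optics.noiseless(), return_masks=True)
    return stack, truth, masks


@pytest.fixture(scope="session")
def noiseless_cone():
    """Ideally focused phantom: fibers converge linearly to the pole point."""
    truth = SpindleGroundTruth.bipolar(divergence=0.0, seed=13)
    stack, truth, masks = generate_spindle_stack(
        truth, Optics.noiseless(), return_masks=True)
    return stack, truth, masks


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study-condition phantom: mild divergence, shot + read noise."""
    truth = SpindleGroundTruth.bipolar(divergence=0.1, seed=17)
    stack, truth, masks = generate_spindle_stack(truth, Optics(),
                                                 return_masks=True)
    return stack, truth, masks
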