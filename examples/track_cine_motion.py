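"""Planar cine motion tracking with beam-gating check.

Simulates an axial cine of a head phantom that steps 5 mm laterally
mid-sequence (with a crossline artifact from interleaved-plane
acquisition), runs the seven-stage tracking pipeline, and checks the
3 mm gating boundary.
"""

import numpy as np
from scipy import ndimage

from brainmrqa.cine import detect_contours, gate_check, track_sequence
from brainmrqa.core import MaskROI
from brainmrqa.synth import CrosslineSpec, PhantomSpec, make_cine, step_schedule

spec = PhantomSpec(noise_sigma=4.0)  # brain SNR ~30, 1.3 mm cine pixels
center = (79.5, 79.5)
seq, truth = make_cine(
    spec,
    schedule=step_schedule(10, 5, dx_mm=5.0, center=center),
    crosslines=[CrosslineSpec("row", 30, 1.5)],
    seed=0,
)

trace = track_sequence(seq)
print("frame  time(s)  dx(mm)  dy(mm)  theta(deg)  score")
for i in range(len(trace)):
    t = trace.transforms[i]
    print(f"{i:4d}  {trace.timestamps[i]:7.1f}  {t.dx_mm:6.2f}  {t.dy_mm:6.2f}"
          f"  {t.theta_deg:9.2f}  {trace.scores[i]:.3f}")
# The dx column shows the programmed 5 mm lateral step appearing at
# frame 5, recovered to a tenth of the 1.3 mm pixel; theta stays at zero.

contours = detect_contours(seq.frames[0])
shifted = MaskROI(ndimage.shift(contours.target_filled.mask.astype(float),
                                (0, 5.0 / 1.3), order=0) > 0.5)
decision = gate_check(shifted, contours.boundary_filled)
print(f"\n5 mm excursion vs 3 mm gating boundary: beam_on={decision.beam_on}, "
      f"{decision.excursion_fraction:.1%} of target outside")
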