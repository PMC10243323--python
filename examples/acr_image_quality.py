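"""ACR image-quality worksheet: uniformity, ghosting, low-contrast score.

Computes the derived ACR metrics from the bundled commissioning ROI
measurements of three receive coils, then verifies the low-contrast
counter on a synthetic spoke phantom where the truth is known.
"""

from brainmrqa.datasets import (
    ACR_GHOSTING_MEANS,
    ACR_LCOD_COUNTS,
    ACR_UNIFORMITY_MEANS,
)
from brainmrqa.qa import full_lcod_score, ghosting_ratio, low_contrast_count, piu
from brainmrqa.synth import make_low_contrast_slice

print("coil          PIU(%)  ghosting  full LCOD")
for coil in ("head_neck", "torso", "brain"):
    g = ACR_GHOSTING_MEANS[coil]
    print(f"{coil:12s}  {piu(*ACR_UNIFORMITY_MEANS[coil]):6.1f}  "
          f"{ghosting_ratio(g['top'], g['bottom'], g['left'], g['right'], g['large_roi']):.3f}"
          f"     {full_lcod_score(ACR_LCOD_COUNTS[coil]):3d}")

# PIU ≥ ~87% and ghosting ≤ 0.025 pass ACR limits; the full LCOD score
# (sum over slices 8–11, max 40) measures contrast resolution — the
# high-resolution brain coil resolves 37 of 40 spokes.

img, template = make_low_contrast_slice([25.0] * 7 + [0.0] * 3,
                                        noise_sigma=5.0, rng=0)
print(f"\nsynthetic LCOD slice: 7 spokes at CNR 5, 3 at CNR 0 -> "
      f"counted {low_contrast_count(img, template)} (expected 7)")
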