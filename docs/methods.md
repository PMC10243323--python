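# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `brainmrqa`, in the spirit of a commissioning report's
methods section.

## Coordinate and motion conventions

Patient axes are x = lateral (left→right), y = anterior→posterior,
z = inferior→superior. Plane images use axial rows = AP / cols = lateral,
sagittal rows = SI / cols = AP, coronal rows = SI / cols = lateral, with
physical position `index × spacing_mm`. In-plane rotation θ is
counterclockwise-positive in (row, col) physical coordinates; 3D rotations
are right-handed about the patient axes — roll about AP, pitch about
lateral, yaw about SI — composed extrinsically as yaw → pitch → roll. The
forward rigid map is `A(q) = c + R(q − c) + t` about a stated center c; the
resamplers realize "move the anatomy by A" as output(x) = input(A⁻¹(x)) with
bi-/trilinear interpolation. With these conventions the plane-to-6-DOF
mapping is exact for separable motions: axial reads (lat, AP, −yaw),
sagittal (AP, SI, −pitch), coronal (lat, SI, +roll); redundant translations
(each seen by two planes) are reconciled by arithmetic mean by default
(`mode="first"` keeps a single-plane readout; the per-plane values are
always retained).

## 2D cine registration

The tracker searches (dx, dy, θ) exhaustively, maximizing the Pearson
correlation between reference-frame ROI intensities and the moving frame
sampled at forward-transformed ROI coordinates (bilinear, rotation about the
filled-contour centroid). Three coarse-to-fine levels — full ±10 mm / ±5° at
2.5 mm / 2.5°, then ±(previous step) at one fifth the step — end at
0.1 mm / 0.1°, so the reported motion is quantized at 0.1 in each DOF.
Candidates are evaluated in a deterministic order sorted by
(|θ|, |dx| + |dy|), so exact score ties resolve to the smallest transform;
an optimum on the edge of the level-0 range sets a truncation flag. ROIs
larger than `max_roi_points` (default 3000) are strided down. Because
correlation is invariant to positive affine intensity maps, the tracker is
insensitive to receiver-gain drift.

Design notes:

- *Contour detection* uses Otsu's threshold in a configurable search box,
  the largest connected component, hole-filling, and a 1-px inner
  perimeter; the gating boundary is the filled target dilated by the 3 mm
  gating margin. This is deliberately parameter-light; the threshold
  box and margins are config-exposed.
- *Overlay inpainting* (stage 4) exists for delivery-console video exports
  whose frames carry burned-in contour graphics. It peels the overlay
  inward, each pass filling unknown pixels with the mean of known
  8-neighbors — exact on locally linear intensity fields. It defaults to
  *off*: raw cine frames carry no graphics, and inpainting intact
  skull-band pixels only blurs the signal the registration needs (measured
  ~0.2 mm bias on a 5 mm step). The overlay is kept at the exact 1-px
  outlines; widening it destroys skull-edge pixels and can anchor the
  registration to the static graphics instead of the moving anatomy.
- *Crossline detection* summarizes each line by the mean intensity of its
  background pixels (the pipeline passes the dilated target mask as the
  exclusion; anatomy chord lengths change too sharply line-to-line to be a
  usable baseline), compares it with the median of the 7 neighboring line
  statistics, and flags residuals beyond k = 5 standard errors, with the
  per-line standard error taken as (robust pixel SD)/√n from the pooled
  background MAD — a large-sample scale estimate that keeps the z-test at
  its nominal false-positive rate. The artifact model (a whole line scaled
  by a constant factor, default 1.5) is a stated surrogate; the true
  interleaved-excitation profile is not characterized here.
- *Registration ROI* is the skull-level band: the filled target dilated by
  4 mm minus eroded by 4 mm, minus any flagged crossline rows/columns.

The brute-force oracle used in tests scans the full fine grid with an
independent scalar implementation and the same tie-break; the optimizer is
required to return its exact argmax on 64×64 instances at matched
resolution.

## 3D mutual-information registration

Repeat-setup volumes are matched with 6-DOF rigid registration maximizing
Shannon mutual information of a 48-bin joint histogram over ROI voxels of
the fixed scan (trilinear sampling of the moving scan at forward-transformed
positions, rotation about the volume center). Optimization is a translation
seed grid (±12 mm at 3 mm) followed by per-DOF coordinate descent at step
sizes 2, 1, 0.5, 0.2 (mm and degrees), sweeping until no DOF improves; a
flat coarse surface raises a registration failure and an optimum at the
range bound (±15 mm / ±10°) sets a truncation flag. MI's invariance to
monotone intensity maps is what the paper-described algorithm class relies
on, and is verified by test. Variability summaries pool *absolute* per-DOF
changes across all later→earlier matches (average, SD with n−1, min, max);
all reported quantities are ≥ 0 by construction.

The registration ROI in tests and examples is the dilated ventricles plus
the skull shell: the ventricle neighborhood localizes translations, while
the skull's long lever arm is what pins sub-degree rotations — with a
ventricle-only ROI on an 80-voxel phantom, 0.5° rotations are near the
information floor.

## MR image-quality metrics

SNR applies the 0.66 factor to a background (air) ROI SD as printed on the
worksheet; in a magnitude image the air noise is Rayleigh-distributed with
SD ≈ 0.655σ of the underlying Gaussian channel noise, so the formula
approximates mean/σ (verified by simulation to within 5%). The noise-ROI
placement is config-free here — the caller supplies both ROIs; the factor
is applied regardless, as the worksheet does. U% and PIU share one
functional form, 100 × (1 − (max − min)/(max + min)), applied to ROI
extremes and to the ACR low/high small-ROI means respectively; PIU is
reported to 1 decimal, ghosting to 3, lengths to 2 (cm) for worksheet
parity. "Discernible" in the low-contrast test is a human judgment; the
automated surrogate counts a circle when its mean exceeds the local annulus
background mean by more than k = 3 × the annulus SD, and human per-slice
counts are accepted directly by `full_lcod_score`. Geometric lengths take
the profile through the center of mass and interpolate the two half-maximum
crossings linearly. The spatial-resolution entry of an ACR report remains a
human reading and is carried as data, not automated.

## Dose-comparison conventions

All percent differences use the calculated dose (or the full ALL model) as
the denominator: 100 × (measured − calculated)/calculated per configuration,
and 100 × (NOC − ALL)/ALL for the modeled attenuation of the whole setup —
the only convention that reproduces the bundled worksheet's printed
percentages from its printed doses. The measured-vs-calculated columns of
the bundled study do not all recompute exactly from the rounded printed
doses (rounding in the source measurements); they are displayed but not
used as test oracles, whereas the TPS-attenuation column recomputes exactly
and is. Dose units are carried as opaque labels; all arithmetic is
ratio-based.

## Synthetic phantoms

The head phantom is an elliptical skull shell (outer semi-axes 75/92/80 mm
lateral/AP/SI, 6 mm thick, intensity 220) around a uniform brain (120) with
mirrored ventricles (55, semi-axes 9/24/14 mm at ±13 mm lateral, −8 mm AP)
on a dark background, at 1.3 mm pixels — the brain-coil cine resolution; a
3.5 mm torso-coil spacing is available through the spec. Dark air pockets
(radius 4.5 mm, intensity 25) embedded mid-shell at irregular angles on the
three cardinal planes emulate sinus/mastoid structure; they are what makes
in-plane rotation observable in a skull-band ROI — a smooth elliptical ring
leaves sub-degree rotations below the information floor, and the
smallest-transform tie-break then reads them as zero. An angular
inner-surface modulation parameter exists but defaults to 0: an off-center
cut through a modulated surface mimics translation and was measured to bias
readouts by ~0.25 mm.

Noise is the magnitude model √((I + n₁)² + n₂²) with n₁, n₂ ~ N(0, σ) —
approximately Gaussian in tissue and Rayleigh in air, the regime the 0.66
SNR factor corrects. The default σ = 4 puts the brain at SNR 30 (a clean
cine); tests use σ = 6 for the SNR-20 conditions. Motion schedules store
the exact transforms applied (no hidden resampling offsets — verified by
registering noiseless frames); session schedules ramp each DOF as
peak × sin²(πs) within labeled segments so programmed per-segment maxima
are exact. Cine timestamps follow the interleaving presets (3 planes →
0.5 fps, 2 → 0.9, 1 → 1.8). All generators are deterministic given a seed.

What the phantoms do *not* emulate: coil-sensitivity shading, k-space
sampling and reconstruction artifacts, through-plane anatomy change during
rotation beyond rigid geometry, susceptibility distortion, and real tissue
texture. Passing the synthetic acceptance therefore demonstrates the
*algorithms* recover programmed rigid motion under stated noise, not that
clinical cine frames will track with the same tolerances.

## Numerical tolerances and degenerate inputs

Registration results are quantized at the final grid step (0.1 mm / 0.1° in
2D, 0.2 in 3D); recovery tests assert ≤ 0.5 px / 0.1° noiseless and
≤ 1 px / 0.5° at SNR 20 for directly applied 2D motion. Frames that pass
through the 3D resample-then-slice path accumulate two trilinear
interpolations, flattening the correlation peak; the recombined 6-DOF
readout is therefore asserted at 0.5 mm / 0.5°, the same class as the 3D
registration tolerance. The double-resampling round trip (apply T then T⁻¹)
leaves large *local* errors at piecewise-constant tissue edges —
interpolation physics, not a transform bug — so round-trip tests bound the
mean (≤ 2% of dynamic range) and median (≈ 0), not the maximum. Degenerate
inputs fail loudly: empty ROIs, zero-variance similarity samples, open
contours that dilation cannot close, overlays covering a whole frame, crop
margins consuming a frame, flat MI surfaces, and non-CT volumes offered for
HU statistics all raise typed errors, with the offending frame index
attached when a pipeline stage fails mid-sequence.

## Problem sizes

Default test and acceptance sizes: 160×160 cine frames (full-size head at
1.3 mm), 64×64 for oracle-equivalence instances, 80³ volumes at 2.5 mm for
3D registration (20-draw success-rate study), 160³ at 1.3 mm for the
three-plane session smoke test, 20 paired simulations for the
crossline-removal comparison. These sizes put every statistical conclusion
at desk scale while keeping each effect comfortably above its measurement
floor.

## Known limitations

- Tracking registers every frame to frame 0; slow drift (e.g., in pitch) is
  reported, not corrected, and no rolling-reference mode is provided.
- The contour detector assumes one bright compact target; multi-structure
  scenes need the search-box config.
- The crossline surrogate scales whole lines; partial-line or multi-line
  correlated artifacts are untested.
- MI registration assumes intensity-comparable volumes (same modality); no
  multi-resolution pyramid is used beyond the translation seed grid, so
  initial offsets beyond ±12 mm need a larger seed range.
- The CLI's `qa report` consumes measured ROI values; fully automatic ACR
  ROI placement on phantom images is not implemented (the image-domain
  pieces — ROI statistics, edge lengths, spoke counting — are).
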