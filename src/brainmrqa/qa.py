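"""MR image-quality metrics: SNR, uniformity, and ACR large-phantom tests.

The battery mirrors a commissioning workflow for receive coils on a
low-field MR-linac: signal-to-noise ratio from a signal ROI and a
background (air) noise ROI, percent uniformity / percent integral
uniformity (PIU) from ROI intensity extremes, percent-signal ghosting
from four edge ROIs and a large central ROI, low-contrast object
detectability (LCOD) spoke counting, and geometric-accuracy lengths via
full-width-at-half-maximum edge finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MaskROI, PlanarImage, ValidationError, VolumeImage

#: Eq.-style correction for Rayleigh-distributed background magnitude noise
RAYLEIGH_FACTOR = 0.66


class ComputationError(ValidationError):
    """A metric's denominator or precondition is degenerate."""


@dataclass(frozen=True)
class ROIStats:
    """Sample statistics of intensities (or HU) inside a mask."""

    mean: float
    sd: float
    max: float
    min: float
    count: int
    roi_area_cm2: float | None = None

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("need min <= mean <= max")
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")
        if self.count < 1:
            raise ValidationError("count must be >= 1")


def roi_stats(image: PlanarImage | VolumeImage, roi: MaskROI) -> ROIStats:
    """Exact sample statistics (n−1 denominator for sd) over an ROI."""
    data = image.pixels if isinstance(image, PlanarImage) else image.voxels
    roi.require_congruent(data)
    roi.require_nonempty()
    vals = data[roi.mask]
    area = None
    if isinstance(image, PlanarImage):
        area = vals.size * image.spacing_mm[0] * image.spacing_mm[1] / 100.0
    return ROIStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size >= 2 else 0.0,
        max=float(vals.max()),
        min=float(vals.min()),
        count=int(vals.size),
        roi_area_cm2=area,
    )


def snr(signal: ROIStats, noise: ROIStats) -> float:
    """SNR = signal mean × 0.66 / noise SD.

    The 0.66 factor corrects the noise SD measured in a background (air)
    ROI of a magnitude image, where the noise is Rayleigh- rather than
    Gaussian-distributed.
    """
    if noise.sd <= 0:
        raise ComputationError("noise ROI has zero standard deviation")
    return signal.mean * RAYLEIGH_FACTOR / noise.sd


def percent_uniformity(roi: ROIStats) -> float:
    """U% = 100 × (1 − (max − min)/(max + min)) over ROI extremes."""
    denom = roi.max + roi.min
    if denom <= 0:
        raise ComputationError("max + min must be positive")
    return 100.0 * (1.0 - (roi.max - roi.min) / denom)


def piu(low_mean: float, high_mean: float) -> float:
    """Percent integral uniformity from the ACR low/high small-ROI means.

    Same functional form as :func:`percent_uniformity`; reported to one
    decimal for parity with ACR worksheets.
    """
    if low_mean > high_mean:
        raise ValidationError("low mean must not exceed high mean")
    if low_mean <= 0:
        raise ValidationError("ROI means must be positive")
    value = 100.0 * (1.0 - (high_mean - low_mean) / (high_mean + low_mean))
    return round(value, 1)


def ghosting_ratio(
    top: float, bottom: float, left: float, right: float, large_roi_mean: float
) -> float:
    """ACR percent-signal ghosting from five ROI means, to 3 decimals.

    ratio = |((top + bottom) − (left + right)) / (2 × large ROI mean)|.
    """
    if large_roi_mean <= 0:
        raise ValidationError("large ROI mean must be positive")
    ratio = abs(((top + bottom) - (left + right)) / (2.0 * large_roi_mean))
    return round(ratio, 3)


# ---------------------------------------------------------------------------
# low-contrast object detectability


@dataclass(frozen=True)
class SpokeTemplate:
    """Circle geometry of a 10-spoke LCOD insert.

    ``spokes`` is a tuple of 10 spokes, each a tuple of three
    ``(center_row, center_col, radius_px)`` circles.
    """

    spokes: tuple
    spacing_mm: float = 1.0

    def __post_init__(self):
        if len(self.spokes) != 10 or any(len(s) != 3 for s in self.spokes):
            raise ValidationError("template needs 10 spokes of 3 circles each")


def low_contrast_count(
    slice_image: PlanarImage, template: SpokeTemplate, k: float = 3.0
) -> int:
    """Count spokes whose three circles are all discernible (0–10).

    Automated surrogate for the human read: a circle is discernible when
    its mean exceeds the local background mean by more than ``k`` × the
    local background SD.  The local background is an annulus two to six
    pixels outside the circle.
    """
    px = slice_image.pixels
    nrow, ncol = px.shape
    rr, cc = np.mgrid[0:nrow, 0:ncol].astype(float)
    count = 0
    for spoke in template.spokes:
        visible = True
        for cr, cc0, rad in spoke:
            if not (0 <= cr < nrow and 0 <= cc0 < ncol):
                raise ValidationError("template circle outside the image")
            d2 = (rr - cr) ** 2 + (cc - cc0) ** 2
            inside = d2 <= rad**2
            annulus = (d2 > (rad + 2) ** 2) & (d2 <= (rad + 6) ** 2)
            if not inside.any() or annulus.sum() < 8:
                raise ValidationError("template circle geometry degenerate")
            bg = px[annulus]
            if not (px[inside].mean() - bg.mean() > k * bg.std(ddof=1)):
                visible = False
                break
        count += int(visible)
    return count


def full_lcod_score(per_slice_counts) -> int:
    """Cumulative LCOD score: sum of the four per-slice spoke counts."""
    counts = list(per_slice_counts)
    if len(counts) != 4:
        raise ValidationError("full LCOD score needs counts for 4 slices")
    for c in counts:
        if int(c) != c or not (0 <= c <= 10):
            raise ValidationError(f"count {c!r} must be an integer in 0–10")
    return int(sum(counts))


# ---------------------------------------------------------------------------
# geometric accuracy


def geometric_lengths(image, axes=("row", "col"), profile_center=None) -> dict:
    """Phantom dimensions by half-maximum edge finding, sub-pixel.

    Takes the intensity profile through the phantom's center of mass
    along each requested axis (``row``/``col`` for a slice, ``x``/``y``/
    ``z`` for a volume), locates the outermost crossings of the half-way
    level between profile min and max by linear interpolation, and
    returns the physical distance between opposing edges in mm.
    """
    if isinstance(image, PlanarImage):
        data, spac, axis_idx = image.pixels, image.spacing_mm, {"row": 0, "col": 1}
    elif isinstance(image, VolumeImage):
        data, spac, axis_idx = image.voxels, image.spacing_mm, {"x": 0, "y": 1, "z": 2}
    else:
        raise ValidationError("image must be a PlanarImage or VolumeImage")
    if profile_center is None:
        from scipy import ndimage

        w = data - data.min()
        if w.sum() == 0:
            raise DetectionEdgeError("image is constant; no edges to find")
        profile_center = ndimage.center_of_mass(w)
    center = [int(round(c)) for c in profile_center]
    out = {}
    for ax in axes:
        if ax not in axis_idx:
            raise ValidationError(f"unknown axis {ax!r} for this image")
        i = axis_idx[ax]
        idx = list(center)
        idx[i] = slice(None)
        profile = data[tuple(idx)].astype(float)
        out[ax] = _fwhm_length(profile, spac[i])
    return out


class DetectionEdgeError(ValidationError):
    """Phantom edge not found along the requested profile."""


def _fwhm_length(profile: np.ndarray, spacing: float) -> float:
    lo, hi = profile.min(), profile.max()
    if hi <= lo:
        raise DetectionEdgeError("flat profile: edge not found")
    half = (lo + hi) / 2.0
    above = profile >= half
    if not above.any() or above[0] or above[-1]:
        raise DetectionEdgeError("phantom touches the profile boundary")
    left = int(np.argmax(above))
    right = len(profile) - 1 - int(np.argmax(above[::-1]))
    # linear interpolation across the two half-maximum crossings
    le = left - 1 + (half - profile[left - 1]) / (profile[left] - profile[left - 1])
    re = right + (profile[right] - half) / (profile[right] - profile[right + 1])
    return float((re - le) * spacing)


# ---------------------------------------------------------------------------
# report container


@dataclass(frozen=True)
class AcrReport:
    """Collected ACR test results for one coil, worksheet-shaped."""

    lcod_counts: dict = field(default_factory=dict)  # slice number → count
    geometric_lengths_cm: dict = field(default_factory=dict)
    uniformity_low: float | None = None
    uniformity_high: float | None = None
    ghosting_rois: dict = field(default_factory=dict)
    spatial_resolution_mm: float | None = None

    def __post_init__(self):
        for s, c in self.lcod_counts.items():
            if int(c) != c or not (0 <= c <= 10):
                raise ValidationError(f"slice {s} count {c!r} not an integer in 0–10")

    @property
    def lcod_full(self) -> int:
        return full_lcod_score([self.lcod_counts[s] for s in sorted(self.lcod_counts)])

    @property
    def piu_percent(self) -> float:
        return piu(self.uniformity_low, self.uniformity_high)

    @property
    def ghosting(self) -> float:
        g = self.ghosting_rois
        return ghosting_ratio(g["top"], g["bottom"], g["left"], g["right"],
                              g["large_roi"])

    def to_dict(self) -> dict:
        """Raw values plus worksheet-rounded strings."""
        out: dict = {"lcod_counts": dict(self.lcod_counts)}
        if len(self.lcod_counts) == 4:
            out["lcod_full"] = self.lcod_full
        if self.uniformity_low is not None:
            out["uniformity"] = {
                "low": self.uniformity_low,
                "high": self.uniformity_high,
                "piu_percent": self.piu_percent,
                "piu_display": f"{self.piu_percent:.1f}",
            }
        if self.ghosting_rois:
            out["ghosting"] = {**self.ghosting_rois, "ratio": self.ghosting,
                               "ratio_display": f"{self.ghosting:.3f}"}
        if self.geometric_lengths_cm:
            out["geometric_lengths_cm"] = {
                k: round(v, 2) for k, v in self.geometric_lengths_cm.items()
            }
        if self.spatial_resolution_mm is not None:
            out["spatial_resolution_mm"] = self.spatial_resolution_mm
        return out
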