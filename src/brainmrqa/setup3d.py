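"""Inter-fraction setup variability by 6-DOF mutual-information registration.

Repeat immobilized setups of the same head are compared by rigid
registration of each later scan to each earlier one (for three scans:
2→1, 3→1, 3→2), using histogram-based mutual information over an ROI —
typically a box around the lateral ventricles, which are well seen on
balanced SSFP localization scans.  The pooled absolute per-DOF changes
summarize how reproducible the mask system is between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DOF_NAMES, MaskROI, RigidTransform3D, ValidationError, VolumeImage


class RegistrationFailure(RuntimeError):
    """The similarity surface gave the optimizer nothing to climb."""


@dataclass(frozen=True)
class SetupMatch:
    """One pairwise rigid match between repeat setup scans."""

    moving_id: str
    fixed_id: str
    transform: RigidTransform3D
    score: float
    roi_label: str = ""
    on_boundary: bool = False

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValidationError("similarity score must be finite")


@dataclass(frozen=True)
class VariabilitySummary:
    """Average / SD / (min, max) of absolute per-DOF changes across matches."""

    average: dict
    sd: dict
    minimum: dict
    maximum: dict
    n_matches: int

    def __post_init__(self):
        for name in DOF_NAMES:
            avg, lo, hi = self.average[name], self.minimum[name], self.maximum[name]
            if lo > hi or min(avg, lo, hi, self.sd[name]) < 0:
                raise ValidationError("summary statistics of |values| must be >= 0 "
                                      "with min <= max")

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "average": self.average,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
        }
        return pd.DataFrame(rows).T[list(DOF_NAMES)]


def summarize_matches(matches) -> VariabilitySummary:
    """Pool |per-DOF values| over matches into the variability summary."""
    matches = list(matches)
    if not matches:
        raise ValidationError("no matches to summarize")
    avg, sd, lo, hi = {}, {}, {}, {}
    for name in DOF_NAMES:
        vals = np.abs([getattr(m.transform, name) for m in matches])
        avg[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if vals.size >= 2 else 0.0
        lo[name] = float(vals.min())
        hi[name] = float(vals.max())
    return VariabilitySummary(avg, sd, lo, hi, len(matches))


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(a, b, bins: int = 48) -> float:
    """Shannon mutual information (nats) of two intensity samples."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px[:, None] * py[None, :])[nz])))


@dataclass(frozen=True)
class Search3DConfig:
    """Coarse translation grid + per-DOF coordinate descent.

    The translation seed scans ±``coarse_range_mm`` at ``coarse_step_mm``.
    Coordinate descent then sweeps all six DOFs at each step size in
    ``descent_steps`` (mm for translations, degrees for rotations),
    repeating a sweep until no DOF improves, so the final resolution is
    the last step (0.2 mm / 0.2°).
    """

    coarse_range_mm: float = 12.0
    coarse_step_mm: float = 3.0
    descent_steps: tuple = (2.0, 1.0, 0.5, 0.2)
    line_reach: int = 3  # candidates per side in a line search
    max_sweeps: int = 6
    bins: int = 48
    max_roi_points: int = 20000
    max_range_mm: float = 15.0
    max_range_deg: float = 10.0


def _roi_points(roi: MaskROI, max_points: int) -> np.ndarray:
    pts = np.array(np.nonzero(roi.mask), dtype=float)  # (3, n)
    if pts.shape[1] > max_points:
        stride = int(np.ceil(pts.shape[1] / max_points))
        pts = pts[:, ::stride]
    return pts


def _mi_of_params(
    params: np.ndarray,
    moving_vx: np.ndarray,
    fixed_vals: np.ndarray,
    pts_phys: np.ndarray,
    center_phys: np.ndarray,
    spacing: np.ndarray,
    bins: int,
) -> float:
    t = RigidTransform3D.from_array(params)
    d = pts_phys - center_phys[:, None]
    src = t.rotation_matrix() @ d + (center_phys + t.translation_mm)[:, None]
    coords = src / spacing[:, None]
    samples = ndimage.map_coordinates(moving_vx, coords, order=1, mode="nearest")
    return mutual_information(fixed_vals, samples, bins)


def rigid_register_3d(
    fixed: VolumeImage,
    moving: VolumeImage,
    roi: MaskROI,
    config: Search3DConfig | None = None,
    moving_id: str = "moving",
    fixed_id: str = "fixed",
) -> SetupMatch:
    """6-DOF rigid registration maximizing mutual information over an ROI.

    The moving volume is sampled (trilinear) at forward-transformed ROI
    voxel positions of the fixed volume; the transform maximizing the MI
    of the sampled-vs-fixed intensity pairs is found by a coarse
    translation grid followed by coordinate descent down to
    0.2 mm / 0.2°.  Rotation is about the fixed volume's physical center.
    """
    config = config or Search3DConfig()
    roi.require_congruent(fixed.voxels)
    roi.require_nonempty()
    spacing = np.asarray(fixed.spacing_mm)
    pts = _roi_points(roi, config.max_roi_points)
    fixed_vals = fixed.voxels[tuple(pts.astype(int))]
    if np.ptp(fixed_vals) == 0:
        raise RegistrationFailure("fixed ROI has no intensity variation")
    pts_phys = pts * spacing[:, None]
    center_phys = (np.asarray(fixed.shape, dtype=float) - 1) / 2 * spacing

    def mi(params):
        return _mi_of_params(params, moving.voxels, fixed_vals, pts_phys,
                             center_phys, spacing, config.bins)

    # stage 1: translation-only grid
    grid1d = np.arange(-config.coarse_range_mm, config.coarse_range_mm + 1e-9,
                       config.coarse_step_mm)
    best = np.zeros(6)
    best_mi = -np.inf
    scores = []
    for tx in grid1d:
        for ty in grid1d:
            for tz in grid1d:
                m = mi(np.array([tx, ty, tz, 0.0, 0.0, 0.0]))
                scores.append(m)
                if m > best_mi:
                    best_mi = m
                    best = np.array([tx, ty, tz, 0.0, 0.0, 0.0])
    if np.ptp(scores) < 1e-12:
        raise RegistrationFailure("similarity surface is flat over the search grid")

    # stage 2: coordinate descent over all six DOFs
    bounds = np.array([config.max_range_mm] * 3 + [config.max_range_deg] * 3)
    on_boundary = False
    for step in config.descent_steps:
        for _ in range(config.max_sweeps):
            improved = False
            for dof in range(6):
                offsets = np.arange(-config.line_reach, config.line_reach + 1) * step
                cands = []
                for off in offsets:
                    v = best[dof] + off
                    if abs(v) <= bounds[dof] + 1e-9:
                        p = best.copy()
                        p[dof] = v
                        cands.append((mi(p), p))
                m, p = max(cands, key=lambda c: c[0])
                if m > best_mi + 1e-12:
                    best_mi, best = m, p
                    improved = True
            if not improved:
                break
    on_boundary = bool(np.any(np.abs(best) > bounds - 1e-9))
    return SetupMatch(
        moving_id=moving_id,
        fixed_id=fixed_id,
        transform=RigidTransform3D.from_array(np.round(best, 9)),
        score=best_mi,
        roi_label=roi.label,
        on_boundary=on_boundary,
    )


def pairwise_setup_variability(
    volumes,
    roi: MaskROI,
    ids=None,
    config: Search3DConfig | None = None,
):
    """Register every later scan to every earlier one and summarize.

    For ``n`` repeat setups this performs all later→earlier matches
    (for 3 scans: 2→1, 3→1, 3→2) with the same ROI on each fixed scan,
    then pools the absolute per-DOF changes into a
    :class:`VariabilitySummary`.  Returns ``(matches, summary)``.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValidationError("need at least 2 setup volumes")
    if ids is None:
        ids = [str(i + 1) for i in range(len(volumes))]
    matches = []
    errors = []
    for i, j in combinations(range(len(volumes)), 2):
        try:
            matches.append(
                rigid_register_3d(volumes[i], volumes[j], roi, config,
                                  moving_id=ids[j], fixed_id=ids[i])
            )
        except RegistrationFailure as e:  # report per pair, keep going
            errors.append((ids[j], ids[i], str(e)))
    if errors and not matches:
        raise RegistrationFailure(f"all pairwise matches failed: {errors}")
    summary = summarize_matches(matches)
    return matches, summary
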