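"""Shared domain types for planar cine frames, MR/CT volumes, masks and rigid motion.

Coordinate conventions
----------------------
* Arrays are 0-indexed ``(row, col)`` for planar images and ``(x, y, z)``
  for volumes, with physical position ``index * spacing_mm``.
* Patient axes: ``x`` = lateral (left→right), ``y`` = anterior→posterior,
  ``z`` = inferior→superior.
* Plane image axes: axial rows = AP, cols = lateral; sagittal rows = SI,
  cols = AP; coronal rows = SI, cols = lateral.
* In-plane rotation ``theta_deg`` is counterclockwise-positive in
  ``(row, col)`` physical coordinates; 3D rotations are right-handed about
  the patient axes (roll about AP, pitch about lateral, yaw about SI),
  applied extrinsically in the fixed order yaw → pitch → roll.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PLANE_LABELS = ("axial", "sagittal", "coronal")

#: cine frame-rate presets (frames/s) by number of interleaved planes
FPS_PRESETS = {3: 0.5, 2: 0.9, 1: 1.8}


class ValidationError(ValueError):
    """Raised when an input violates a documented type invariant."""


def _wrap_angle(theta_deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    t = float(theta_deg) % 360.0
    if t > 180.0:
        t -= 360.0
    return t


@dataclass(frozen=True)
class PlanarImage:
    """A single 2D MR frame with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Scalar intensities; finite.
    spacing_mm : (float, float)
        Physical size of one pixel along (row, col); strictly positive.
    plane_label : {"axial", "sagittal", "coronal"}
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    plane_label: str = "axial"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("pixel intensities must be finite")
        sp = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValidationError(f"spacing must be positive, got {sp}")
        if self.plane_label not in PLANE_LABELS:
            raise ValidationError(f"unknown plane label {self.plane_label!r}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PlanarCineSequence:
    """Time-ordered planar cine frames for one anatomical plane.

    All frames share shape and spacing.  ``timestamps`` default to
    ``frame_index / frame_rate_fps`` and must be nondecreasing.
    """

    frames: tuple[PlanarImage, ...]
    frame_rate_fps: float
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        frames = tuple(self.frames)
        if not frames:
            raise ValidationError("cine sequence needs at least one frame")
        if float(self.frame_rate_fps) <= 0:
            raise ValidationError("frame rate must be positive")
        shape = frames[0].shape
        spacing = frames[0].spacing_mm
        plane = frames[0].plane_label
        for i, f in enumerate(frames):
            if f.shape != shape or f.spacing_mm != spacing or f.plane_label != plane:
                raise ValidationError(
                    f"frame {i} does not match frame 0 (shape/spacing/plane)"
                )
        if self.timestamps is None:
            ts = np.arange(len(frames), dtype=float) / float(self.frame_rate_fps)
        else:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (len(frames),):
                raise ValidationError("one timestamp per frame required")
            if np.any(np.diff(ts) < 0):
                raise ValidationError("timestamps must be nondecreasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_rate_fps", float(self.frame_rate_fps))
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def plane_label(self) -> str:
        return self.frames[0].plane_label

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return self.frames[0].spacing_mm


@dataclass(frozen=True)
class VolumeImage:
    """A 3D MR or CT volume indexed (x, y, z) with spacing in mm.

    Axes follow the patient convention: x lateral, y anterior→posterior,
    z inferior→superior.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "MR"

    def __post_init__(self):
        vx = np.asarray(self.voxels, dtype=float)
        if vx.ndim != 3 or vx.size == 0:
            raise ValidationError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(vx)):
            raise ValidationError("voxel intensities must be finite")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be 3 positive values, got {sp}")
        if self.modality not in ("MR", "CT"):
            raise ValidationError(f"modality must be MR or CT, got {self.modality!r}")
        object.__setattr__(self, "voxels", vx)
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class MaskROI:
    """Binary region of interest congruent with its host image."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask).astype(bool)
        if m.size == 0:
            raise ValidationError("mask must be non-empty")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.count == 0:
            raise ValidationError(f"ROI {self.label!r} selects no pixels")

    def require_congruent(self, other) -> None:
        shape = other.shape if hasattr(other, "shape") else other
        if self.mask.shape != tuple(shape):
            raise ValidationError(
                f"ROI shape {self.mask.shape} does not match image shape {tuple(shape)}"
            )


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: translation (mm) and one rotation (deg).

    ``dx_mm`` moves along columns, ``dy_mm`` along rows; ``theta_deg``
    rotates counterclockwise about ``center`` (a (row, col) pixel
    coordinate).  The forward map in physical (row, col) mm coordinates is
    ``A(q) = c + R(theta) (q - c) + (dy, dx)``.
    """

    dx_mm: float = 0.0
    dy_mm: float = 0.0
    theta_deg: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        vals = (self.dx_mm, self.dy_mm, self.theta_deg, *self.center)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("transform parameters must be finite")
        object.__setattr__(self, "dx_mm", float(self.dx_mm))
        object.__setattr__(self, "dy_mm", float(self.dy_mm))
        object.__setattr__(self, "theta_deg", _wrap_angle(self.theta_deg))
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def is_identity(self) -> bool:
        return self.dx_mm == 0.0 and self.dy_mm == 0.0 and self.theta_deg == 0.0

    def magnitude(self) -> tuple[float, float]:
        """(|theta|, |dx|+|dy|) used for deterministic tie-breaking."""
        return (abs(self.theta_deg), abs(self.dx_mm) + abs(self.dy_mm))


@dataclass(frozen=True)
class RigidTransform3D:
    """6-DOF rigid motion in patient axes.

    Translations in mm along lateral / AP / SI; rotations in degrees:
    roll about the AP axis, pitch about the lateral axis, yaw about the SI
    axis, composed extrinsically in the order yaw → pitch → roll.
    """

    lat_mm: float = 0.0
    ap_mm: float = 0.0
    si_mm: float = 0.0
    roll_deg: float = 0.0
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0

    def __post_init__(self):
        vals = (self.lat_mm, self.ap_mm, self.si_mm,
                self.roll_deg, self.pitch_deg, self.yaw_deg)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("transform parameters must be finite")
        for name in ("lat_mm", "ap_mm", "si_mm"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("roll_deg", "pitch_deg", "yaw_deg"):
            object.__setattr__(self, name, _wrap_angle(getattr(self, name)))

    @property
    def translation_mm(self) -> np.ndarray:
        return np.array([self.lat_mm, self.ap_mm, self.si_mm])

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.roll_deg, self.pitch_deg, self.yaw_deg])

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation acting on (x, y, z) offsets, yaw then pitch then roll."""
        rr, rp, ry = np.deg2rad([self.roll_deg, self.pitch_deg, self.yaw_deg])
        cy, sy = np.cos(ry), np.sin(ry)
        yaw = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
        cp, sp = np.cos(rp), np.sin(rp)
        pitch = np.array([[1.0, 0.0, 0.0], [0.0, cp, -sp], [0.0, sp, cp]])
        cr, sr = np.cos(rr), np.sin(rr)
        roll = np.array([[cr, 0.0, sr], [0.0, 1.0, 0.0], [-sr, 0.0, cr]])
        return roll @ pitch @ yaw

    def as_array(self) -> np.ndarray:
        return np.array([self.lat_mm, self.ap_mm, self.si_mm,
                         self.roll_deg, self.pitch_deg, self.yaw_deg])

    @classmethod
    def from_array(cls, a) -> "RigidTransform3D":
        a = np.asarray(a, dtype=float)
        return cls(lat_mm=a[0], ap_mm=a[1], si_mm=a[2],
                   roll_deg=a[3], pitch_deg=a[4], yaw_deg=a[5])


DOF_NAMES = ("roll_deg", "pitch_deg", "yaw_deg", "lat_mm", "ap_mm", "si_mm")
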