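"""Synthetic digital phantoms with known ground truth.

Everything the toolkit's tests and examples need is generated here rather
than taken from clinical scans: head cross-sections (bright skull ring,
mid-intensity brain, dark ventricles) under programmed rigid motion with
interleaved-plane "crossline" line artifacts, 3D head volumes for setup
registration, and ACR-like uniform and low-contrast QA phantom slices.

Noise model: frames are magnitude images, ``sqrt((I + n1)^2 + n2^2)`` with
``n1, n2 ~ N(0, sigma)`` — approximately Gaussian inside anatomy and
Rayleigh-distributed in air, which is the regime the 0.66 factor of the
background-ROI SNR formula corrects for.  All generators are deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    FPS_PRESETS,
    MaskROI,
    PlanarCineSequence,
    PlanarImage,
    RigidTransform2D,
    RigidTransform3D,
    ValidationError,
    VolumeImage,
)
from .qa import SpokeTemplate

#: semi-axis order everywhere: (lateral, AP, SI), mm
_AXES = ("lat", "ap", "si")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of the digital head phantom.

    Semi-axes are (lateral, AP, SI) in mm.  Intensities are arbitrary MR
    units; the defaults give a bright skull ring over a mid-intensity
    brain with dark ventricles.  ``noise_sigma`` is the per-channel
    Gaussian sigma of the magnitude-image noise model.
    """

    skull_semiaxes_mm: tuple[float, float, float] = (75.0, 92.0, 80.0)
    skull_thickness_mm: float = 6.0
    #: optional fractional angular modulation of the inner skull surface
    skull_thickness_variation: float = 0.0
    #: air pockets (sinuses, mastoid cells) embedded in the skull shell.
    #: Real skulls are not smooth rings; these sharp dark features give the
    #: skull band the tangential texture that makes rotation observable,
    #: and being rigid 3D structures they read out without bias when the
    #: cut plane shifts.  Radius 0 disables them.
    sinus_radius_mm: float = 4.5
    intensity_sinus: float = 25.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (9.0, 24.0, 14.0)
    ventricle_offset_mm: tuple[float, float, float] = (13.0, -8.0, 0.0)
    intensity_background: float = 0.0
    intensity_skull: float = 220.0
    intensity_brain: float = 120.0
    intensity_ventricle: float = 55.0
    noise_sigma: float = 4.0
    spacing_mm: float = 1.3

    def __post_init__(self):
        if min(self.skull_semiaxes_mm) <= 0 or self.skull_thickness_mm <= 0:
            raise ValidationError("geometry parameters must be positive")
        if min(self.ventricle_semiaxes_mm) <= 0 or self.spacing_mm <= 0:
            raise ValidationError("geometry parameters must be positive")
        if not (0 <= self.skull_thickness_variation < 0.5):
            raise ValidationError("thickness variation must be in [0, 0.5)")
        inner = np.array(self.skull_semiaxes_mm) - self.skull_thickness_mm
        if np.any(inner <= 0):
            raise ValidationError("skull thickness exceeds skull semi-axes")
        # both mirrored ventricles must fit inside the brain, including the
        # deepest inward excursion of the modulated inner skull surface
        reach = np.abs(np.array(self.ventricle_offset_mm)) + np.array(
            self.ventricle_semiaxes_mm
        )
        if np.any(reach >= inner * (1.0 - self.skull_thickness_variation)):
            raise ValidationError("ventricles must nest strictly inside the brain")


#: which (col, row) patient axes span each plane's image grid
PLANE_AXES = {"axial": ("lat", "ap"), "sagittal": ("ap", "si"), "coronal": ("lat", "si")}


def _plane_coords(shape, spacing, plane):
    """Physical (col_axis, row_axis) offsets from image center, mm."""
    nrow, ncol = shape
    rr, cc = np.mgrid[0:nrow, 0:ncol].astype(float)
    row_mm = (rr - (nrow - 1) / 2) * spacing
    col_mm = (cc - (ncol - 1) / 2) * spacing
    return col_mm, row_mm


def _ellipse(u, v, cu, cv, au, av):
    return ((u - cu) / au) ** 2 + ((v - cv) / av) ** 2 <= 1.0


def _inner_skull_mask(xyz_mm, semiaxes, variation):
    """Ellipsoid with an angularly modulated surface (inner skull table).

    ``xyz_mm`` are the three patient-axis offsets from the head center
    (arrays; an absent axis is all-zero for a 2D slice).  The surface
    radius is scaled by ``1 - variation * p(u)`` with
    ``p = u_x u_y + u_y u_z + u_z u_x`` over direction cosines — a smooth
    pattern that breaks rotational symmetry in all three cardinal planes.
    """
    x, y, z = xyz_mm
    r = np.sqrt(x**2 + y**2 + z**2)
    r = np.where(r == 0, 1.0, r)
    p = (x * y + y * z + z * x) / r**2
    rho = np.sqrt(
        (x / semiaxes[0]) ** 2 + (y / semiaxes[1]) ** 2 + (z / semiaxes[2]) ** 2
    )
    return rho <= 1.0 - variation * p


#: in-plane angles (deg) of the skull air pockets for each cardinal plane;
#: irregular spacing so no symmetry survives
_SINUS_ANGLES = {
    "axial": (10.0, 95.0, 150.0, 260.0, 315.0),
    "sagittal": (35.0, 120.0, 225.0, 300.0),
    "coronal": (60.0, 165.0, 250.0, 340.0),
}


def _sinus_centers_mm(spec: PhantomSpec):
    """3D centers of the skull air pockets, mid-shell, on cardinal planes."""
    outer = np.array(spec.skull_semiaxes_mm)
    mid = outer - spec.skull_thickness_mm / 2.0
    centers = []
    for plane, angles in _SINUS_ANGLES.items():
        ia, ib = (_AXES.index(a) for a in PLANE_AXES[plane])
        for ang in angles:
            c = np.zeros(3)
            c[ia] = mid[ia] * np.cos(np.deg2rad(ang))
            c[ib] = mid[ib] * np.sin(np.deg2rad(ang))
            centers.append(c)
    return centers


def make_head_slice(
    spec: PhantomSpec | None = None,
    plane: str = "axial",
    shape: tuple[int, int] = (160, 160),
    noise_sigma: float | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Render one noiseless-or-noisy head cross-section plus tissue masks.

    Returns ``(PlanarImage, masks)`` where ``masks`` holds boolean arrays
    for ``head`` (everything inside the skull), ``skull``, ``brain`` and
    ``ventricles``, strictly nested by construction.
    """
    spec = spec or PhantomSpec()
    if plane not in PLANE_AXES:
        raise ValidationError(f"unknown plane {plane!r}")
    ax_c, ax_r = PLANE_AXES[plane]
    ic, ir = _AXES.index(ax_c), _AXES.index(ax_r)
    col_mm, row_mm = _plane_coords(shape, spec.spacing_mm, plane)

    outer = np.array(spec.skull_semiaxes_mm)
    inner = outer - spec.skull_thickness_mm
    head = _ellipse(col_mm, row_mm, 0, 0, outer[ic], outer[ir])
    xyz = [np.zeros(shape), np.zeros(shape), np.zeros(shape)]
    xyz[ic] = col_mm
    xyz[ir] = row_mm
    brain = _inner_skull_mask(xyz, inner, spec.skull_thickness_variation)
    brain &= head
    skull = head & ~brain
    voff = np.array(spec.ventricle_offset_mm)
    vax = np.array(spec.ventricle_semiaxes_mm)
    vent = np.zeros(shape, dtype=bool)
    for sign in (+1.0, -1.0):  # mirrored pair across the midline
        off = voff.copy()
        off[0] *= sign
        vent |= _ellipse(col_mm, row_mm, off[ic], off[ir], vax[ic], vax[ir])
    vent &= brain

    sinus = np.zeros(shape, dtype=bool)
    if spec.sinus_radius_mm > 0:
        i3 = ({0, 1, 2} - {ic, ir}).pop()
        for c in _sinus_centers_mm(spec):
            d = c[i3]
            if abs(d) >= spec.sinus_radius_mm:
                continue
            r_in_plane = np.sqrt(spec.sinus_radius_mm**2 - d**2)
            sinus |= ((col_mm - c[ic]) ** 2 + (row_mm - c[ir]) ** 2) <= r_in_plane**2
        sinus &= skull

    img = np.full(shape, spec.intensity_background, dtype=float)
    img[brain] = spec.intensity_brain
    img[skull] = spec.intensity_skull
    img[sinus] = spec.intensity_sinus
    img[vent] = spec.intensity_ventricle
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        img = _magnitude_noise(img, sigma, _as_rng(rng))
    masks = {"head": head, "skull": skull & ~sinus, "brain": brain & ~vent,
             "ventricles": vent, "sinus": sinus}
    image = PlanarImage(img, (spec.spacing_mm, spec.spacing_mm), plane)
    return image, masks


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _magnitude_noise(img: np.ndarray, sigma: float, rng: np.random.Generator):
    n1 = rng.normal(0.0, sigma, img.shape)
    n2 = rng.normal(0.0, sigma, img.shape)
    return np.sqrt((img + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# rigid resampling (shared forward-map convention with the trackers)


def apply_rigid_2d(image: PlanarImage, transform: RigidTransform2D) -> PlanarImage:
    """Move the pictured anatomy by ``transform`` (bilinear resampling).

    A point at physical position q moves to ``A(q) = c + R(θ)(q−c) + t``,
    so the output pixel at x takes the input value at ``A⁻¹(x)``.
    """
    sp = np.asarray(image.spacing_mm)
    nrow, ncol = image.shape
    rr, cc = np.mgrid[0:nrow, 0:ncol].astype(float)
    x = np.stack([rr * sp[0], cc * sp[1]])  # physical (row, col) mm
    c = np.asarray(transform.center) * sp
    t = np.array([transform.dy_mm, transform.dx_mm])
    th = np.deg2rad(transform.theta_deg)
    cos, sin = np.cos(th), np.sin(th)
    d0 = x[0] - c[0] - t[0]
    d1 = x[1] - c[1] - t[1]
    src0 = (cos * d0 + sin * d1 + c[0]) / sp[0]
    src1 = (-sin * d0 + cos * d1 + c[1]) / sp[1]
    out = ndimage.map_coordinates(image.pixels, [src0, src1], order=1, mode="nearest")
    return PlanarImage(out, image.spacing_mm, image.plane_label)


def apply_rigid_3d(volume: VolumeImage, transform: RigidTransform3D) -> VolumeImage:
    """3D analogue of :func:`apply_rigid_2d` (trilinear resampling).

    Rotation is about the volume's physical center; translations follow
    patient axes (lat, AP, SI) = array axes (x, y, z).
    """
    sp = np.asarray(volume.spacing_mm)
    nx, ny, nz = volume.shape
    grid = np.mgrid[0:nx, 0:ny, 0:nz].astype(float)
    x = grid * sp[:, None, None, None]
    c = (np.array([nx, ny, nz], dtype=float) - 1) / 2 * sp
    t = transform.translation_mm
    Rinv = transform.rotation_matrix().T
    d = x - (c + t)[:, None, None, None]
    src = np.einsum("ij,jxyz->ixyz", Rinv, d) + c[:, None, None, None]
    src /= sp[:, None, None, None]
    out = ndimage.map_coordinates(
        volume.voxels, src.reshape(3, -1), order=1, mode="nearest"
    ).reshape(volume.shape)
    return VolumeImage(out, volume.spacing_mm, volume.modality)


def extract_plane(volume: VolumeImage, plane: str, index: int | None = None) -> PlanarImage:
    """Central (or indexed) orthogonal slice with this package's plane axes.

    Axial rows = AP, cols = lateral; sagittal rows = SI, cols = AP;
    coronal rows = SI, cols = lateral.
    """
    vx, sp = volume.voxels, volume.spacing_mm
    if plane == "axial":
        k = volume.shape[2] // 2 if index is None else index
        return PlanarImage(vx[:, :, k].T, (sp[1], sp[0]), "axial")
    if plane == "sagittal":
        k = volume.shape[0] // 2 if index is None else index
        return PlanarImage(vx[k, :, :].T, (sp[2], sp[1]), "sagittal")
    if plane == "coronal":
        k = volume.shape[1] // 2 if index is None else index
        return PlanarImage(vx[:, k, :].T, (sp[2], sp[0]), "coronal")
    raise ValidationError(f"unknown plane {plane!r}")


def make_head_volume(
    spec: PhantomSpec | None = None,
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_mm: float = 2.0,
    noise_sigma: float | None = None,
    rng=None,
):
    """3D head phantom; returns (VolumeImage, masks) like the slice maker."""
    spec = spec or PhantomSpec()
    grid = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    ctr = (np.asarray(shape, dtype=float) - 1) / 2
    xyz = (grid - ctr[:, None, None, None]) * voxel_mm

    def ellipsoid(center, axes):
        s = ((xyz[0] - center[0]) / axes[0]) ** 2
        s += ((xyz[1] - center[1]) / axes[1]) ** 2
        s += ((xyz[2] - center[2]) / axes[2]) ** 2
        return s <= 1.0

    outer = np.array(spec.skull_semiaxes_mm)
    inner = outer - spec.skull_thickness_mm
    head = ellipsoid((0, 0, 0), outer)
    if head[0].any() or head[-1].any() or head[:, 0].any() or head[:, -1].any():
        raise ValidationError("phantom does not fit in the requested volume shape")
    brain = _inner_skull_mask(list(xyz), inner, spec.skull_thickness_variation)
    brain &= head
    skull = head & ~brain
    vent = np.zeros(shape, dtype=bool)
    voff = np.array(spec.ventricle_offset_mm)
    for sign in (+1.0, -1.0):
        off = voff.copy()
        off[0] *= sign
        vent |= ellipsoid(off, spec.ventricle_semiaxes_mm)
    vent &= brain

    sinus = np.zeros(shape, dtype=bool)
    if spec.sinus_radius_mm > 0:
        for c in _sinus_centers_mm(spec):
            d2 = (xyz[0] - c[0]) ** 2 + (xyz[1] - c[1]) ** 2 + (xyz[2] - c[2]) ** 2
            sinus |= d2 <= spec.sinus_radius_mm**2
        sinus &= skull

    img = np.full(shape, spec.intensity_background, dtype=float)
    img[brain] = spec.intensity_brain
    img[skull] = spec.intensity_skull
    img[sinus] = spec.intensity_sinus
    img[vent] = spec.intensity_ventricle
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        img = _magnitude_noise(img, sigma, _as_rng(rng))
    masks = {"head": head, "skull": skull & ~sinus, "brain": brain & ~vent,
             "ventricles": vent, "sinus": sinus}
    return VolumeImage(img, (voxel_mm,) * 3, "MR"), masks


# ---------------------------------------------------------------------------
# motion schedules and cine generation


@dataclass(frozen=True)
class MotionSchedule:
    """Per-frame ground-truth rigid motion with segment labels."""

    transforms: tuple
    segment_labels: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self):
        if len(self.transforms) != len(self.segment_labels):
            raise ValidationError("one segment label per frame required")
        object.__setattr__(self, "transforms", tuple(self.transforms))
        object.__setattr__(self, "segment_labels", tuple(self.segment_labels))

    def __len__(self) -> int:
        return len(self.transforms)

    def segments(self) -> dict[str, tuple[int, int]]:
        """label → (first frame, last frame), for contiguous labels."""
        out: dict[str, tuple[int, int]] = {}
        for i, lab in enumerate(self.segment_labels):
            if lab in out:
                out[lab] = (out[lab][0], i)
            else:
                out[lab] = (i, i)
        return out


def static_schedule(n_frames: int, center=(0.0, 0.0)) -> MotionSchedule:
    return MotionSchedule(
        tuple(RigidTransform2D(center=center) for _ in range(n_frames)),
        ("static",) * n_frames,
    )


def step_schedule(
    n_frames: int,
    step_frame: int,
    dx_mm: float = 0.0,
    dy_mm: float = 0.0,
    theta_deg: float = 0.0,
    center=(0.0, 0.0),
) -> MotionSchedule:
    """Identity until ``step_frame``, then a constant offset."""
    ts, labels = [], []
    for i in range(n_frames):
        if i < step_frame:
            ts.append(RigidTransform2D(center=center))
            labels.append("baseline")
        else:
            ts.append(RigidTransform2D(dx_mm, dy_mm, theta_deg, center))
            labels.append("shifted")
    return MotionSchedule(tuple(ts), tuple(labels))


def session_schedule_3d(
    segments: list[tuple[str, int, dict]],
) -> MotionSchedule:
    """Programmed 6-DOF session: per-segment smooth bumps with known maxima.

    ``segments`` is a list of ``(label, n_frames, peaks)`` where ``peaks``
    maps DOF names (``lat_mm`` … ``yaw_deg``) to the peak excursion.  Each
    DOF follows ``peak * sin^2(pi * s)`` across its segment, so the
    programmed per-segment maximum |excursion| equals ``peak`` exactly
    (segments of ≥ 3 frames hit the midpoint).
    """
    transforms, labels = [], []
    for label, n, peaks in segments:
        if n < 1:
            raise ValidationError("segments need at least one frame")
        for i in range(n):
            s = (i + 0.5) / n if n > 2 else 0.0
            w = np.sin(np.pi * s) ** 2 if n > 2 else 0.0
            # guarantee the exact peak at the middle frame of odd segments
            if n > 2 and i == n // 2 and n % 2 == 1:
                w = 1.0
            kw = {k: v * w for k, v in peaks.items()}
            transforms.append(RigidTransform3D(**kw))
            labels.append(label)
    return MotionSchedule(tuple(transforms), tuple(labels))


@dataclass(frozen=True)
class CrosslineSpec:
    """Injected interleaved-plane line artifact: scale one full line."""

    axis: str = "row"
    index: int = 0
    factor: float = 1.5
    frames: tuple[int, ...] | str = "all"


def make_cine(
    spec: PhantomSpec | None = None,
    plane: str = "axial",
    schedule: MotionSchedule | None = None,
    crosslines: list[CrosslineSpec] | None = None,
    n_planes: int = 3,
    shape: tuple[int, int] = (160, 160),
    seed: int | None = 0,
    border_px: int = 0,
    burn_contours: bool = False,
):
    """Render a cine sequence from a schedule; returns (sequence, schedule).

    Frame i is the noiseless head slice moved by ``schedule[i]`` plus
    magnitude noise, optional crossline artifacts, and an optional
    constant system border of ``border_px`` pixels.  The frame rate is
    the interleaving preset for ``n_planes`` planes (3 → 0.5 fps,
    2 → 0.9 fps, 1 → 1.8 fps).  ``burn_contours`` draws bright target and
    gating-boundary outlines at their frame-0 positions into every frame,
    emulating graphics burned into delivery-console video exports.
    """
    spec = spec or PhantomSpec()
    if schedule is None:
        schedule = static_schedule(30, center=((shape[0] - 1) / 2, (shape[1] - 1) / 2))
    if n_planes not in FPS_PRESETS:
        raise ValidationError("n_planes must be 1, 2, or 3")
    fps = FPS_PRESETS[n_planes]
    rng = _as_rng(seed)
    base, masks = make_head_slice(spec, plane, shape, noise_sigma=0.0)
    head = masks["head"]
    graphics = None
    if burn_contours:
        outline = head & ~ndimage.binary_erosion(head)
        margin_px = max(1, int(round(3.0 / spec.spacing_mm)))
        dil = ndimage.binary_dilation(head, iterations=margin_px)
        boundary = dil & ~ndimage.binary_erosion(dil)
        graphics = outline | boundary
    frames = []
    for i, tr in enumerate(schedule.transforms):
        if not isinstance(tr, RigidTransform2D):
            raise ValidationError("planar cine needs a 2D schedule")
        moved = apply_rigid_2d(base, tr)
        moved_head = (
            apply_rigid_2d(
                PlanarImage(head.astype(float), base.spacing_mm, plane), tr
            ).pixels
            > 0.5
        )
        if _touches_edge(moved_head):
            raise ValidationError(f"frame {i}: motion moves anatomy outside the frame")
        px = moved.pixels
        if spec.noise_sigma > 0:
            px = _magnitude_noise(px, spec.noise_sigma, rng)
        if graphics is not None:
            px = px.copy()
            px[graphics] = 1.5 * spec.intensity_skull
        for cl in crosslines or []:
            if cl.frames == "all" or i in cl.frames:
                if cl.axis == "row":
                    px[cl.index, :] *= cl.factor
                else:
                    px[:, cl.index] *= cl.factor
        if border_px > 0:
            px = np.pad(px, border_px, mode="constant", constant_values=0.0)
        frames.append(PlanarImage(px, base.spacing_mm, plane))
    seq = PlanarCineSequence(tuple(frames), fps)
    return seq, schedule


def _touches_edge(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def make_cine_3planes(
    spec: PhantomSpec | None = None,
    schedule: MotionSchedule | None = None,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_mm: float = 2.6,
    seed: int | None = 0,
):
    """Three orthogonal cine sequences from one 3D motion schedule.

    Renders the head volume moved by each frame's 6-DOF transform and
    extracts the three central orthogonal slices, emulating interleaved
    three-plane acquisition (0.5 fps).  Returns ``(dict of sequences,
    schedule)``.
    """
    spec = spec or PhantomSpec()
    if schedule is None:
        schedule = session_schedule_3d([("static", 10, {})])
    rng = _as_rng(seed)
    vol, _ = make_head_volume(spec, shape, voxel_mm, noise_sigma=0.0)
    frames = {p: [] for p in PLANE_AXES}
    for tr in schedule.transforms:
        if not isinstance(tr, RigidTransform3D):
            raise ValidationError("three-plane cine needs a 3D schedule")
        moved = apply_rigid_3d(vol, tr)
        for p in PLANE_AXES:
            sl = extract_plane(moved, p)
            px = sl.pixels
            if spec.noise_sigma > 0:
                px = _magnitude_noise(px, spec.noise_sigma, rng)
            frames[p].append(PlanarImage(px, sl.spacing_mm, p))
    fps = FPS_PRESETS[3]
    seqs = {p: PlanarCineSequence(tuple(frames[p]), fps) for p in PLANE_AXES}
    return seqs, schedule


# ---------------------------------------------------------------------------
# QA phantoms


def make_uniform_phantom(
    shape: tuple[int, int] = (256, 256),
    spacing_mm: float = 1.0,
    diameter_mm: float | tuple[float, float] = 170.0,
    signal: float = 1000.0,
    noise_sigma: float = 0.0,
    ghost_fraction: float = 0.0,
    intensity_range: tuple[float, float] | None = None,
    phase_axis: str = "row",
    rng=None,
):
    """Uniform (or ramped) disk phantom with optional N/2 ghost replicas.

    ``diameter_mm`` may be a scalar (disk) or (row, col) pair (ellipse).
    ``intensity_range=(low, high)`` replaces the flat signal with a linear
    column-direction ramp whose in-disk extremes are exactly (low, high).
    ``ghost_fraction`` adds a half-field-of-view replica along
    ``phase_axis`` at that fractional intensity.  Returns (image, mask).
    """
    if ghost_fraction < 0:
        raise ValidationError("ghost fraction must be nonnegative")
    d = (diameter_mm, diameter_mm) if np.isscalar(diameter_mm) else diameter_mm
    nrow, ncol = shape
    if d[0] / spacing_mm >= nrow or d[1] / spacing_mm >= ncol:
        raise ValidationError("phantom does not fit in the image")
    col_mm, row_mm = _plane_coords(shape, spacing_mm, "axial")
    disk = _ellipse(col_mm, row_mm, 0, 0, d[1] / 2, d[0] / 2)
    img = np.zeros(shape, dtype=float)
    if intensity_range is None:
        img[disk] = signal
    else:
        low, high = intensity_range
        cols = col_mm[disk]
        ramp = low + (high - low) * (cols - cols.min()) / (cols.max() - cols.min())
        img[disk] = ramp
    if ghost_fraction > 0:
        ghost = np.roll(img, nrow // 2 if phase_axis == "row" else ncol // 2,
                        axis=0 if phase_axis == "row" else 1)
        img = img + ghost_fraction * ghost
    if noise_sigma > 0:
        img = _magnitude_noise(img, noise_sigma, _as_rng(rng))
    return PlanarImage(img, (spacing_mm, spacing_mm)), MaskROI(disk, "phantom")


def make_low_contrast_slice(
    contrasts,
    noise_sigma: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    spacing_mm: float = 1.0,
    background: float = 1000.0,
    rng=None,
):
    """ACR-style low-contrast slice: 10 spokes of three circles each.

    ``contrasts`` gives the intensity of each spoke's circles above the
    in-disk background (10 values, outermost spoke first).  Circle radii
    shrink toward the disk edge as in the ACR insert.  Returns
    ``(PlanarImage, SpokeTemplate)`` for the detectability counter.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.shape != (10,):
        raise ValidationError("exactly 10 spoke contrasts required")
    nrow, ncol = shape
    ctr = ((nrow - 1) / 2, (ncol - 1) / 2)
    disk_r = min(nrow, ncol) * 0.42
    col_mm, row_mm = _plane_coords(shape, spacing_mm, "axial")
    disk = _ellipse(col_mm, row_mm, 0, 0, disk_r * spacing_mm, disk_r * spacing_mm)
    img = np.zeros(shape, dtype=float)
    img[disk] = background

    radii_px = (7.0, 5.5, 4.0)  # circle sizes, center → edge
    ring_r = (disk_r * 0.30, disk_r * 0.55, disk_r * 0.80)
    rr, cc = np.mgrid[0:nrow, 0:ncol].astype(float)
    spokes = []
    for k in range(10):
        ang = -np.pi / 2 + k * 2 * np.pi / 10
        circles = []
        for ring, rad in zip(ring_r, radii_px):
            cr = ctr[0] + ring * np.sin(ang)
            cc0 = ctr[1] + ring * np.cos(ang)
            inside = (rr - cr) ** 2 + (cc - cc0) ** 2 <= rad**2
            img[inside] += contrasts[k]
            circles.append((float(cr), float(cc0), float(rad)))
        spokes.append(tuple(circles))
    if noise_sigma > 0:
        img = _magnitude_noise(img, noise_sigma, _as_rng(rng))
    template = SpokeTemplate(spokes=tuple(spokes), spacing_mm=spacing_mm)
    return PlanarImage(img, (spacing_mm, spacing_mm)), template
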