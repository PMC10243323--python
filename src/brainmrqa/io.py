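"""Readers and writers for standard medical image formats and motion traces.

All downstream modules consume the domain types from
:mod:`brainmrqa.core`; this module is the only place raw files are
touched.  Supported inputs: DICOM series (directory of single-frame
files), NIfTI volumes, and PNG/TIFF frame stacks (a directory of
same-shaped rasters, sorted by filename, or one multi-page TIFF).
Motion traces round-trip through CSV at six-decimal precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import tifffile
import yaml

from .cine import MotionTrace, SixDofTrace
from .core import (
    PlanarCineSequence,
    PlanarImage,
    ValidationError,
    VolumeImage,
)

_RASTER_EXT = (".png", ".tif", ".tiff")


def read_image_series(
    path,
    format: str = "auto",
    spacing_mm=None,
    plane_label: str = "axial",
    frame_rate_fps: float = 0.5,
    modality: str = "MR",
):
    """Read a cine frame stack or a volume from disk.

    ``format`` is one of ``auto``, ``dicom_cine``, ``dicom_volume``,
    ``nifti``, ``raster_stack``.  DICOM and NIfTI carry their own
    spacing; raster stacks need ``spacing_mm`` (defaults to the 1.3 mm
    cine pixel size when omitted).  Returns a
    :class:`~brainmrqa.core.PlanarCineSequence` for cine inputs or a
    :class:`~brainmrqa.core.VolumeImage` for volumes.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format == "nifti":
        return _read_nifti(path, modality)
    if format in ("dicom_cine", "dicom_volume"):
        return _read_dicom(path, format, plane_label, frame_rate_fps, modality)
    if format == "raster_stack":
        sp = spacing_mm or (1.3, 1.3)
        if np.isscalar(sp):
            sp = (sp, sp)
        return _read_raster_stack(path, sp, plane_label, frame_rate_fps)
    raise ValidationError(f"unknown format {format!r}")


def _sniff_format(path: Path) -> str:
    if path.is_file():
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            return "nifti"
        if name.endswith(_RASTER_EXT):
            return "raster_stack"
        if name.endswith(".dcm"):
            return "dicom_cine"
        raise IOError(f"cannot infer format of {path}")
    entries = sorted(p for p in path.iterdir() if p.is_file())
    if not entries:
        raise IOError(f"directory {path} is empty")
    if any(p.suffix.lower() == ".dcm" for p in entries):
        return "dicom_cine"
    if any(p.suffix.lower() in _RASTER_EXT for p in entries):
        return "raster_stack"
    raise IOError(f"no readable image files in {path}")


def _read_nifti(path: Path, modality: str) -> VolumeImage:
    try:
        img = nib.load(str(path))
    except Exception as e:
        raise IOError(f"cannot read NIfTI file {path}: {e}") from e
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(data, tuple(float(z) for z in zooms), modality)


def _read_dicom(path: Path, format: str, plane_label: str, fps: float, modality: str):
    files = [path] if path.is_file() else sorted(
        p for p in path.iterdir() if p.suffix.lower() == ".dcm"
    )
    if not files:
        raise IOError(f"no DICOM files in {path}")
    dsets = []
    for f in files:
        try:
            dsets.append(pydicom.dcmread(str(f)))
        except Exception as e:
            raise IOError(f"cannot read DICOM file {f}: {e}") from e
    dsets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    arrays = [d.pixel_array.astype(float) for d in dsets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent frame shapes in series: {shapes}")
    ps = getattr(dsets[0], "PixelSpacing", [1.0, 1.0])
    spacing = (float(ps[0]), float(ps[1]))
    if format == "dicom_volume":
        thick = float(getattr(dsets[0], "SliceThickness", 1.0))
        vol = np.stack(arrays, axis=-1)  # slices along z
        return VolumeImage(np.transpose(vol, (1, 0, 2)), (spacing[1], spacing[0], thick),
                           modality)
    frames = tuple(PlanarImage(a, spacing, plane_label) for a in arrays)
    return PlanarCineSequence(frames, fps)


def _read_raster_stack(path: Path, spacing, plane_label: str, fps: float):
    if path.is_file():
        if path.suffix.lower() in (".tif", ".tiff"):
            stack = tifffile.imread(str(path))
        else:
            stack = iio.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
        arrays = [np.asarray(fr, dtype=float) for fr in stack]
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _RASTER_EXT)
        if not files:
            raise IOError(f"no raster files in {path}")
        arrays = []
        for f in files:
            try:
                arrays.append(np.asarray(iio.imread(str(f)), dtype=float))
            except Exception as e:
                raise IOError(f"cannot read raster file {f}: {e}") from e
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent frame shapes in stack: {shapes}")
    frames = tuple(PlanarImage(a, spacing, plane_label) for a in arrays)
    return PlanarCineSequence(frames, fps)


# ---------------------------------------------------------------------------
# writers


def write_cine_tiff(seq: PlanarCineSequence, path) -> None:
    """Write a cine sequence as one float32 multi-page TIFF."""
    stack = np.stack([f.pixels for f in seq.frames]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def write_volume_nifti(vol: VolumeImage, path) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))


def write_trace(trace, path) -> None:
    """Write a motion trace as CSV, one row per frame, 6-decimal floats.

    Accepts a per-plane :class:`~brainmrqa.cine.MotionTrace`
    (time_s, dx_mm, dy_mm, theta_deg, score) or a 6-DOF
    :class:`~brainmrqa.cine.SixDofTrace`.
    """
    if not isinstance(trace, (MotionTrace, SixDofTrace)):
        raise ValidationError("trace must be a MotionTrace or SixDofTrace")
    df = trace.to_frame()
    if df.empty:
        raise ValidationError("cannot write an empty trace")
    try:
        df.to_csv(path, index=False, float_format="%.6f")
    except OSError as e:
        raise IOError(f"cannot write trace to {path}: {e}") from e


def read_trace(path) -> pd.DataFrame:
    """Read a trace CSV back as a DataFrame (lossless at 6 decimals)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration


def load_yaml_config(path, allowed_keys=None) -> dict:
    """Load a YAML mapping, rejecting unknown keys when a schema is given."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return cfg
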