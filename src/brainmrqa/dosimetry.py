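"""Immobilization attenuation accounting and dose-comparison arithmetic.

Covers the dosimetric commissioning bookkeeping for an MR-linac brain
treatment package: Hounsfield-unit statistics of contoured immobilization
components on CT, and measured-vs-calculated percent dose differences for
beams delivered through different subsets of the hardware (with/without
the overlay board and the receive coils).

Configuration labels: ``ALL`` = overlay board and coils modeled in the
calculation, ``NC`` = no coils, ``NO`` = no overlay, ``NOC`` = neither.
The modeled attenuation of the full setup is the NOC-vs-ALL percent
change, referenced to ALL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MaskROI, ValidationError, VolumeImage

CONFIG_KEYS = ("ALL", "NC", "NO", "NOC")


@dataclass(frozen=True)
class HuStructureStats:
    """Mean ± SD (max) of HU inside a contoured structure."""

    label: str
    mean_hu: float
    sd_hu: float
    max_hu: float

    def __post_init__(self):
        if self.sd_hu < 0:
            raise ValidationError("sd must be nonnegative")
        if self.max_hu < -1024 or self.mean_hu < -1024:
            raise ValidationError("HU below the CT scale floor (-1024)")

    def __str__(self) -> str:
        return f"{self.mean_hu:.0f} ± {self.sd_hu:.1f} ({self.max_hu:.0f})"


def hu_roi_stats(ct: VolumeImage, structure: MaskROI, label: str = "") -> HuStructureStats:
    """HU statistics of a contoured structure on a CT volume."""
    if ct.modality != "CT":
        raise ValidationError("HU statistics require a CT volume")
    structure.require_congruent(ct.voxels)
    structure.require_nonempty()
    vals = ct.voxels[structure.mask]
    return HuStructureStats(
        label=label or structure.label,
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=1)) if vals.size >= 2 else 0.0,
        max_hu=float(vals.max()),
    )


@dataclass(frozen=True)
class DoseComparisonRecord:
    """Measured dose and per-configuration calculated doses for one beam."""

    gantry_angle_deg: float
    measured_dose: float
    calculated: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.measured_dose <= 0:
            raise ValidationError("doses must be positive")
        for key, dose in self.calculated.items():
            if key not in CONFIG_KEYS:
                raise ValidationError(f"unknown configuration {key!r}")
            if dose <= 0:
                raise ValidationError("doses must be positive")


def percent_dose_difference(measured: float, calculated: float) -> float:
    """100 × (measured − calculated) / calculated, to 2 decimals."""
    if calculated <= 0:
        raise ValidationError("calculated dose must be positive")
    return round(100.0 * (measured - calculated) / calculated, 2)


def tps_attenuation(dose_all: float, dose_noc: float) -> float:
    """Modeled attenuation of the full setup: 100 × (NOC − ALL)/ALL.

    NOC is the calculation with neither overlay nor coils; ALL models
    both, so the difference is the dose the hardware removes.  Two
    decimals.
    """
    if dose_all <= 0 or dose_noc <= 0:
        raise ValidationError("doses must be positive")
    return round(100.0 * (dose_noc - dose_all) / dose_all, 2)


def attenuation_report(
    records,
    tolerance_percent: float = 2.0,
    tps_column: bool | str = "auto",
) -> pd.DataFrame:
    """Per-angle percent differences for every configuration present.

    One row per record; columns ``pct_diff_<CFG>`` give the measured-vs-
    calculated difference for each configuration the record carries, and
    ``tps_attenuation_pct`` gives the modeled full-setup attenuation when
    both ALL and NOC calculations exist (``tps_column=True`` makes the
    pair mandatory).  ``exceeds_tolerance`` flags rows where any percent
    difference exceeds ``tolerance_percent`` in magnitude.
    """
    records = list(records)
    if not records:
        raise ValidationError("no dose comparison records supplied")
    for rec in records:
        if not rec.calculated:
            raise ValidationError("each record needs at least one calculated dose")
    if tps_column is True:
        for rec in records:
            if "ALL" not in rec.calculated or "NOC" not in rec.calculated:
                raise ValidationError(
                    "TPS attenuation column requires ALL and NOC doses for every record"
                )
    include_tps = tps_column is True or (
        tps_column == "auto"
        and all("ALL" in r.calculated and "NOC" in r.calculated for r in records)
    )
    rows = []
    for rec in records:
        row: dict = {
            "gantry_angle_deg": rec.gantry_angle_deg,
            "measured_dose": rec.measured_dose,
        }
        diffs = []
        for cfg in CONFIG_KEYS:
            if cfg in rec.calculated:
                d = percent_dose_difference(rec.measured_dose, rec.calculated[cfg])
                row[f"pct_diff_{cfg}"] = d
                diffs.append(d)
        if include_tps:
            row["tps_attenuation_pct"] = tps_attenuation(
                rec.calculated["ALL"], rec.calculated["NOC"]
            )
        row["exceeds_tolerance"] = any(abs(d) > tolerance_percent for d in diffs)
        rows.append(row)
    return pd.DataFrame(rows)
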