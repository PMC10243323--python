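"""Bundled example commissioning measurements.

Worked-example inputs from an ACR large-phantom image-quality evaluation
and an immobilization-attenuation study of a low-field MR-linac brain
treatment package: per-coil ACR worksheet ROI means and spoke counts,
per-gantry-angle ion-chamber doses with treatment-planning-system
calculations for different hardware subsets, and the end-to-end point
dose pair.  These are measurement *inputs*; every derived quantity (PIU,
ghosting ratio, LCOD score, percent differences, modeled attenuation) is
computed by the package.
"""

from __future__ import annotations

import pandas as pd

from .dosimetry import DoseComparisonRecord

#: ACR uniformity small-ROI means (low, high) per coil, slice 7
ACR_UNIFORMITY_MEANS = {
    "head_neck": (702.75, 759.16),
    "torso": (741.27, 757.2),
    "brain": (2193.23, 2517.25),
}

#: ACR ghosting ROI means per coil, slice 7
ACR_GHOSTING_MEANS = {
    "head_neck": dict(top=20.6, bottom=21.2, left=33.5, right=40.9, large_roi=733.2),
    "torso": dict(top=24.7, bottom=23.3, left=36.9, right=35.0, large_roi=749.6),
    "brain": dict(top=26.4, bottom=26.1, left=24.0, right=21.0, large_roi=2295.3),
}

#: LCOD spoke counts per coil for slices 8, 9, 10, 11 (in that order)
ACR_LCOD_COUNTS = {
    "head_neck": (1, 8, 9, 10),
    "torso": (3, 8, 9, 10),
    "brain": (8, 9, 10, 10),
}

#: measured dose and per-configuration calculated doses by gantry angle.
#: ALL models overlay board + coils; NC drops the coils; NO drops the
#: overlay; NOC drops both.
DOSE_COMPARISON = {
    180: dict(measured=71.3, ALL=71.0, NC=70.7, NO=72.8, NOC=72.9),
    160: dict(measured=70.7, ALL=70.0, NC=70.4, NO=72.4, NOC=72.2),
    140: dict(measured=69.0, ALL=69.0, NC=70.0, NO=69.6, NOC=69.5),
    120: dict(measured=74.2, ALL=73.4, NC=72.6, NO=73.2, NOC=72.9),
    90: dict(measured=83.9, ALL=83.0, NC=83.4, NO=83.4, NOC=82.9),
}

#: end-to-end IMRT point dose: measured vs. calculated with overlay+coils modeled
E2E_POINT_DOSE = dict(measured=206.06, calculated_all=206.8)


def dose_comparison_records() -> list[DoseComparisonRecord]:
    """The bundled attenuation study as DoseComparisonRecord objects."""
    return [
        DoseComparisonRecord(
            gantry_angle_deg=float(angle),
            measured_dose=row["measured"],
            calculated={k: row[k] for k in ("ALL", "NC", "NO", "NOC")},
        )
        for angle, row in DOSE_COMPARISON.items()
    ]


def dose_comparison_frame() -> pd.DataFrame:
    """Same study as a DataFrame matching the CLI's CSV input columns."""
    rows = [
        dict(gantry_angle=angle, measured=r["measured"], dose_ALL=r["ALL"],
             dose_NC=r["NC"], dose_NO=r["NO"], dose_NOC=r["NOC"])
        for angle, r in DOSE_COMPARISON.items()
    ]
    return pd.DataFrame(rows)
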