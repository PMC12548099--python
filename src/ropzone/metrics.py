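"""Per-eye biomarkers: RAL summaries, AVR, zone ratio and zone label.

The area of vascularized retina (AVR) is computed with the spherical-cap
surface-area formula exactly as used clinically,

    AVR = (pi * AL^2 / 2) * (1 - cos(meanRAL / AL)),

with the axial length AL entering both as the cap prefactor and as the
radius in the cap angle ``meanRAL/AL``.  The two roles imply different
effective eye radii (AL is the *diameter* of the globe); the formula is
nevertheless applied verbatim because the published group-mean areas are
reproduced only in this form.  :func:`true_cap_area` gives the geometric
cap area ``2*pi*r^2*(1 - cos(s/r))`` for a sphere of radius ``r`` and
arclength ``s`` and serves as the phantom reference.

The mathematical zone label uses the ICROP constructions: zone I is the
circle of radius twice the disc-to-fovea distance (min-RAL < 2*FD, strict),
and posterior zone II extends two disc diameters beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import MeasurementError

__all__ = [
    "EyeMetrics",
    "ZoneClassification",
    "spherical_cap_avr",
    "true_cap_area",
    "classify_zone_math",
    "summarize_metrics",
    "METRICS_COLUMNS",
]

#: CSV column order for one eye; measurement names follow the clinical table.
METRICS_COLUMNS = [
    "AL",
    "FD",
    "mean-RAL",
    "min-RAL",
    "min-RAL:FD ratio",
    "AVR",
    "assessed_angle",
    "zone_math",
    "cap_angle_rad",
    "n_border_samples",
    "n_dropped_samples",
    "n_interpolated_cells",
    "fd_chord_mm",
]


class ZoneClassification(NamedTuple):
    """Zone label plus the continuous min-RAL:FD ratio behind it."""

    label: str
    zone_ratio: float


@dataclass
class EyeMetrics:
    """All per-eye biomarkers derived from one UWF-OCT volume."""

    axial_length_mm: float
    foveal_distance_mm: float
    ral_mm: np.ndarray
    mean_ral_mm: float
    min_ral_mm: float
    zone_ratio: float
    avr_mm2: float
    cap_angle_rad: float
    assessed_angle_deg: float
    zone_math: str
    n_border_samples: int
    n_dropped_samples: int = 0
    n_interpolated_cells: int = 0
    fd_chord_mm: float = float("nan")

    def to_row(self) -> dict:
        """One flat CSV row with the clinical column names."""
        return {
            "AL": self.axial_length_mm,
            "FD": self.foveal_distance_mm,
            "mean-RAL": self.mean_ral_mm,
            "min-RAL": self.min_ral_mm,
            "min-RAL:FD ratio": self.zone_ratio,
            "AVR": self.avr_mm2,
            "assessed_angle": self.assessed_angle_deg,
            "zone_math": self.zone_math,
            "cap_angle_rad": self.cap_angle_rad,
            "n_border_samples": self.n_border_samples,
            "n_dropped_samples": self.n_dropped_samples,
            "n_interpolated_cells": self.n_interpolated_cells,
            "fd_chord_mm": self.fd_chord_mm,
        }


def spherical_cap_avr(mean_ral: float, al: float) -> float:
    """Area of vascularized retina (mm^2) by the verbatim cap formula.

    ``(pi * al^2 / 2) * (1 - cos(mean_ral / al))``; ``mean_ral`` may range
    up to ``pi * al`` (the full sphere in this parameterization).
    """
    if al <= 0:
        raise MeasurementError("axial length must be positive")
    if mean_ral < 0:
        raise MeasurementError("mean RAL must be non-negative")
    if mean_ral > np.pi * al:
        raise MeasurementError(
            f"mean RAL {mean_ral:g} exceeds pi*AL = {np.pi * al:g} "
            "(beyond the full sphere)"
        )
    return float(np.pi * al**2 / 2.0 * (1.0 - np.cos(mean_ral / al)))


def true_cap_area(radius: float, arclength: float) -> float:
    """Geometric spherical-cap area ``2*pi*r^2*(1-cos(s/r))`` (reference).

    Exact for a sphere of radius ``radius`` and a cap whose geodesic
    radius (arclength from the pole) is ``arclength``; used to quantify
    how the clinical formula deviates from true geometry on phantoms.
    """
    if radius <= 0:
        raise MeasurementError("sphere radius must be positive")
    if not 0 <= arclength <= np.pi * radius:
        raise MeasurementError("arclength must lie in [0, pi*radius]")
    return float(2.0 * np.pi * radius**2 * (1.0 - np.cos(arclength / radius)))


def classify_zone_math(min_ral: float, fd: float, disc_diameter: float = 1.1) -> ZoneClassification:
    """Mathematical zone from min-RAL, foveal distance and disc diameter.

    Zone I iff ``min_ral < 2*fd`` (strict: a border exactly on the zone I
    circle is not inside it); posterior zone II ("PII") iff
    ``min_ral < 2*fd + 2*disc_diameter``; otherwise "II+".  The continuous
    ``min_ral/fd`` ratio is returned alongside the label.
    """
    if min(min_ral, fd, disc_diameter) <= 0:
        raise MeasurementError("zone classification needs positive inputs")
    ratio = min_ral / fd
    if min_ral < 2.0 * fd:
        label = "I"
    elif min_ral < 2.0 * fd + 2.0 * disc_diameter:
        label = "PII"
    else:
        label = "II+"
    return ZoneClassification(label=label, zone_ratio=ratio)


def summarize_metrics(
    ral: np.ndarray,
    fd: float,
    al: float,
    assessed_angle_deg: float,
    disc_diameter: float = 1.1,
    n_dropped: int = 0,
    n_interpolated: int = 0,
    fd_chord_mm: float = float("nan"),
) -> EyeMetrics:
    """Assemble the full per-eye biomarker record from the RAL array.

    The mean is the unweighted arithmetic mean of all retained samples.
    """
    ral = np.asarray(ral, dtype=float)
    if ral.size == 0:
        raise MeasurementError("cannot summarize an empty RAL array")
    mean_ral = float(ral.mean())
    min_ral = float(ral.min())
    zone = classify_zone_math(min_ral, fd, disc_diameter)
    return EyeMetrics(
        axial_length_mm=float(al),
        foveal_distance_mm=float(fd),
        ral_mm=ral,
        mean_ral_mm=mean_ral,
        min_ral_mm=min_ral,
        zone_ratio=zone.zone_ratio,
        avr_mm2=spherical_cap_avr(mean_ral, al),
        cap_angle_rad=mean_ral / al,
        assessed_angle_deg=float(assessed_angle_deg),
        zone_math=zone.label,
        n_border_samples=int(ral.size),
        n_dropped_samples=int(n_dropped),
        n_interpolated_cells=int(n_interpolated),
        fd_chord_mm=float(fd_chord_mm),
    )
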