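"""End-to-end per-eye measurement: volume + landmarks → biomarkers.

This is the glue the command line wraps: extract the RPE surface, build
the disc and border chains, resample the border at the configured angular
density over the temporal hemisphere, measure geodesics, and assemble the
:class:`~ropzone.metrics.EyeMetrics` record.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import AnnotationError
from .geodesics import compute_ral, geodesic_distance
from .geometry import ScanGeometry, estimate_axial_length
from .landmarks import (
    LandmarkSet,
    assessed_angle,
    build_border_chain,
    disc_centroid_3d,
    resample_border,
)
from .metrics import EyeMetrics, summarize_metrics
from .surface import LabelVolume, RpeSurface, extract_rpe_surface

__all__ = ["RunConfig", "MeasureOutput", "measure_eye"]


@dataclass
class RunConfig:
    """Tunable measurement parameters (defaults are the study settings)."""

    density: int = 10  # border samples per 30-degree clock hour
    disc_diameter_mm: float = 1.1
    neighborhood: int = 16  # geodesic graph connectivity (8 or 16)
    interp_radius: float = 5.0  # cells; RPE interpolation reach for chains
    n_reps: int = 2000  # bootstrap replicates (cohort analyses)
    seed: int = 0
    measured_al_mm: float | None = None  # metadata AL takes precedence

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MeasureOutput:
    """Metrics plus the intermediate objects useful for QC plots."""

    metrics: EyeMetrics
    surface: RpeSurface
    border_samples: np.ndarray  # (M, 3)
    border_cells: np.ndarray  # (M, 2)
    disc_center_enface: np.ndarray  # (2,)


def measure_eye(
    vol: LabelVolume,
    landmarks: LandmarkSet,
    config: RunConfig | None = None,
) -> MeasureOutput:
    """Run the full measurement chain on one segmented eye."""
    config = config or RunConfig()
    geom: ScanGeometry = vol.geom
    landmarks.check_bounds(geom)

    surface = extract_rpe_surface(vol)
    disc = disc_centroid_3d(
        landmarks.disc_edge, surface, geom, interp_radius=config.interp_radius
    )
    chain = build_border_chain(
        landmarks.border_points, surface, geom, interp_radius=config.interp_radius
    )
    sampled = resample_border(
        chain, disc, landmarks.fovea, density=config.density,
        laterality=landmarks.laterality,
    )
    if len(sampled.points3d) == 0:
        raise AnnotationError("no border samples in the temporal hemisphere")

    ral = compute_ral(surface, geom, disc, sampled.points3d,
                      neighborhood=config.neighborhood)
    al = estimate_axial_length(surface, landmarks.fovea, geom,
                               measured_al=config.measured_al_mm)
    fd = geodesic_distance(
        surface, geom, disc.position3d,
        surface.point_at(float(landmarks.fovea[0]), float(landmarks.fovea[1])),
        neighborhood=config.neighborhood,
    )
    fd_chord = float(np.linalg.norm(
        surface.point_at(float(landmarks.fovea[0]), float(landmarks.fovea[1]))
        - disc.position3d
    ))
    angle = assessed_angle(chain, disc, landmarks.fovea)

    metrics = summarize_metrics(
        ral,
        fd=fd,
        al=al,
        assessed_angle_deg=angle,
        disc_diameter=config.disc_diameter_mm,
        n_dropped=len(sampled.points3d) - len(ral),
        n_interpolated=chain.n_interpolated + disc.n_interpolated,
        fd_chord_mm=fd_chord,
    )
    return MeasureOutput(
        metrics=metrics,
        surface=surface,
        border_samples=sampled.points3d,
        border_cells=sampled.cells,
        disc_center_enface=disc.enface_center,
    )
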