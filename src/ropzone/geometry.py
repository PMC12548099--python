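"""Scan-to-space coordinate model for a single-pivot fan-beam OCT scanner.

The scanner is modeled as a pencil of rays through one pivot point: each
A-scan is a straight ray whose direction is set by two scan angles, and
depth samples are spaced evenly along the ray.  Voxel indices are ordered
``(fast, slow, depth)``, 0-based, with fractional indices permitted (they
interpolate linearly in angle and depth).

Angle convention
----------------
For index ``fast`` the scan angle is ``alpha = (fast/(n_fast-1) - 1/2) *
fov_fast_deg`` and analogously ``beta`` for ``slow``.  The ray direction is
obtained by rotating the central axis (+z) first by ``alpha`` about the
slow axis (y), then by ``beta`` about the fast axis (x):

    d(alpha, beta) = (sin(alpha), -sin(beta) cos(alpha), cos(beta) cos(alpha))

The physical position of ``(fast, slow, depth)`` is
``d * (pivot_offset_mm + depth * depth_step_mm)`` with the origin at the
pivot.  Two consequences worth remembering: points on the same ray are
separated by exactly ``depth_step_mm`` per depth index, and the angular
spacing between adjacent fast (or slow) indices is constant.

Axial length is estimated from the radial distance of the RPE at the fovea
through an affine calibration ``AL = al_scale * r_fovea + al_offset_mm``.
The phantom profile puts the pivot at the globe center, where ``al_scale=2``
makes the estimate exactly twice the retinal radius.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, FormatError, GeometryError, MeasurementError

__all__ = [
    "ScanGeometry",
    "voxel_to_physical",
    "physical_to_voxel",
    "estimate_axial_length",
    "load_geometry",
    "save_geometry",
]

_FIELDS = (
    "n_fast",
    "n_slow",
    "n_depth",
    "fov_fast_deg",
    "fov_slow_deg",
    "depth_step_mm",
    "pivot_offset_mm",
    "al_scale",
    "al_offset_mm",
)


@dataclass
class ScanGeometry:
    """Parameterization of the fan-beam scan-to-space transform.

    Parameters
    ----------
    n_fast, n_slow, n_depth
        A-scans per B-scan, B-scans per volume, depth samples per A-scan.
    fov_fast_deg, fov_slow_deg
        Full angular field of view along each scan axis, degrees.
    depth_step_mm
        Axial sample spacing along the ray, mm.
    pivot_offset_mm
        Radial distance from the pivot to depth sample 0, mm.
    al_scale, al_offset_mm
        Affine calibration mapping the radial foveal RPE distance to axial
        length.  ``al_scale=2, al_offset_mm=0`` is the central-pivot
        (phantom) profile.
    """

    n_fast: int
    n_slow: int
    n_depth: int
    fov_fast_deg: float
    fov_slow_deg: float
    depth_step_mm: float
    pivot_offset_mm: float = 0.0
    al_scale: float = 1.0
    al_offset_mm: float = 0.0
    _dir_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if min(self.n_fast, self.n_slow, self.n_depth) < 2:
            raise ConfigurationError("all grid counts must be >= 2")
        for name in ("fov_fast_deg", "fov_slow_deg"):
            fov = getattr(self, name)
            if not 0.0 < fov <= 180.0:
                raise ConfigurationError(f"{name} must lie in (0, 180], got {fov}")
        if self.depth_step_mm <= 0:
            raise ConfigurationError("depth_step_mm must be positive")
        if self.pivot_offset_mm < 0:
            raise ConfigurationError("pivot_offset_mm must be non-negative")

    # -- angle helpers ---------------------------------------------------

    def angles_rad(self, fast, slow):
        """Scan angles (alpha, beta) in radians for fractional indices."""
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        alpha = (fast / (self.n_fast - 1) - 0.5) * np.deg2rad(self.fov_fast_deg)
        beta = (slow / (self.n_slow - 1) - 0.5) * np.deg2rad(self.fov_slow_deg)
        return alpha, beta

    def index_of_angles(self, alpha, beta):
        """Inverse of :meth:`angles_rad` (fractional indices)."""
        fast = (np.asarray(alpha) / np.deg2rad(self.fov_fast_deg) + 0.5) * (self.n_fast - 1)
        slow = (np.asarray(beta) / np.deg2rad(self.fov_slow_deg) + 0.5) * (self.n_slow - 1)
        return fast, slow

    def directions(self, fast, slow) -> np.ndarray:
        """Unit ray directions for (arrays of) en-face indices, shape (...,3)."""
        alpha, beta = self.angles_rad(fast, slow)
        sa, ca = np.sin(alpha), np.cos(alpha)
        sb, cb = np.sin(beta), np.cos(beta)
        return np.stack([sa, -sb * ca, cb * ca], axis=-1)

    def direction_grid(self) -> np.ndarray:
        """Unit ray directions for every column, shape (n_fast, n_slow, 3).

        Cached: the grid is reused by surface lifting, the geodesic graph
        and the phantom generator.
        """
        if self._dir_cache is None:
            ff, ss = np.meshgrid(
                np.arange(self.n_fast), np.arange(self.n_slow), indexing="ij"
            )
            self._dir_cache = self.directions(ff, ss)
        return self._dir_cache

    def radius_mm(self, depth):
        """Radial distance from the pivot for a fractional depth index."""
        return self.pivot_offset_mm + np.asarray(depth, dtype=float) * self.depth_step_mm

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_dir_cache")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        unknown = set(d) - set(_FIELDS)
        if unknown:
            raise FormatError(f"unknown scan-geometry fields: {sorted(unknown)}")
        missing = {"n_fast", "n_slow", "n_depth", "fov_fast_deg", "fov_slow_deg", "depth_step_mm"} - set(d)
        if missing:
            raise FormatError(f"missing scan-geometry fields: {sorted(missing)}")
        return cls(**d)


def _check_bounds(index: np.ndarray, geom: ScanGeometry) -> None:
    limits = (geom.n_fast - 1, geom.n_slow - 1, geom.n_depth - 1)
    names = ("fast", "slow", "depth")
    for ax in range(3):
        vals = index[..., ax]
        if np.any(vals < 0) or np.any(vals > limits[ax]):
            raise GeometryError(
                f"{names[ax]} index out of range [0, {limits[ax]}]"
            )


def voxel_to_physical(index, geom: ScanGeometry, check_bounds: bool = True) -> np.ndarray:
    """Map voxel indices ``(fast, slow, depth)`` to physical mm coordinates.

    ``index`` may be a single triple or an array of shape (..., 3);
    fractional indices are allowed (linear in angle and depth).  The origin
    is the scan pivot and the central axis is +z.
    """
    index = np.asarray(index, dtype=float)
    if index.shape[-1] != 3:
        raise GeometryError("index must have shape (..., 3)")
    if check_bounds:
        _check_bounds(index, geom)
    d = geom.directions(index[..., 0], index[..., 1])
    r = geom.radius_mm(index[..., 2])
    return d * r[..., None]


def physical_to_voxel(points, geom: ScanGeometry) -> np.ndarray:
    """Inverse of :func:`voxel_to_physical`: ray angles plus radial solve.

    Returns fractional ``(fast, slow, depth)``.  Points at the pivot (r=0)
    are rejected because every ray passes through them.
    """
    p = np.asarray(points, dtype=float)
    r = np.linalg.norm(p, axis=-1)
    if np.any(r <= 0):
        raise GeometryError("cannot invert a point at the scan pivot")
    u = p / r[..., None]
    alpha = np.arcsin(np.clip(u[..., 0], -1.0, 1.0))
    beta = np.arctan2(-u[..., 1], u[..., 2])
    fast, slow = geom.index_of_angles(alpha, beta)
    depth = (r - geom.pivot_offset_mm) / geom.depth_step_mm
    return np.stack([fast, slow, depth], axis=-1)


def estimate_axial_length(surface, fovea, geom: ScanGeometry, measured_al: float | None = None) -> float:
    """Axial length (mm) from the radial RPE distance at the fovea.

    ``AL = al_scale * (pivot_offset + z_rpe(fovea) * depth_step) + al_offset``.
    A metadata-supplied ``measured_al`` takes precedence and bypasses the
    estimate entirely.
    """
    if measured_al is not None:
        return float(measured_al)
    z = surface.z_at(fovea[0], fovea[1])
    if not np.isfinite(z):
        raise MeasurementError(
            f"fovea at ({fovea[0]}, {fovea[1]}) falls on an invalid surface column"
        )
    return float(geom.al_scale * geom.radius_mm(z) + geom.al_offset_mm)


def load_geometry(path) -> ScanGeometry:
    """Read a scan-geometry sidecar (YAML or JSON by extension)."""
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse scan geometry {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise FormatError(f"scan geometry {path} is not a mapping")
    return ScanGeometry.from_dict(d)


def save_geometry(geom: ScanGeometry, path) -> None:
    path = Path(path)
    d = geom.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
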