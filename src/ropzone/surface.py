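"""RPE surface, retinal thickness map and en face projection.

The input is a label volume with voxel classes 0=background, 1=retina,
2=choroid, as produced by B-scan segmentation.  Because the segmentation
has no explicit RPE class, the RPE is taken as the half-voxel interface
between the last retina voxel and the first choroid voxel on each A-scan
— the retina/choroid boundary, whose height is stable with disease
severity.  Thickness is counted along the ray (per A-scan), matching how
retinal depth maps are displayed, and is an approximation to true
perpendicular thickness on tilted surface regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantViolationError
from .geometry import ScanGeometry

__all__ = [
    "LabelVolume",
    "RpeSurface",
    "ThicknessMap",
    "extract_rpe_surface",
    "thickness_map",
    "enface_projection",
    "BACKGROUND",
    "RETINA",
    "CHOROID",
]

log = logging.getLogger(__name__)

BACKGROUND, RETINA, CHOROID = 0, 1, 2


@dataclass
class LabelVolume:
    """Segmented OCT volume, axes ``(fast, slow, depth)``, labels {0,1,2}."""

    voxels: np.ndarray
    geom: ScanGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        expected = (self.geom.n_fast, self.geom.n_slow, self.geom.n_depth)
        if v.shape != expected:
            raise InvariantViolationError(
                f"volume shape {v.shape} does not match geometry grid {expected}"
            )
        if v.size and v.max() > CHOROID:
            raise InvariantViolationError(
                f"labels must be in {{0,1,2}}, found {int(v.max())}"
            )
        self.voxels = v.astype(np.uint8, copy=False)


@dataclass
class RpeSurface:
    """Per-column fractional depth of the retina/choroid interface.

    ``z_rpe`` is NaN on invalid columns (those lacking retina or choroid).
    ``n_multirun_columns`` counts columns where segmentation noise produced
    more than one retina run along the ray.
    """

    z_rpe: np.ndarray
    valid: np.ndarray
    geom: ScanGeometry
    n_multirun_columns: int = 0
    _points_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def z_at(self, fast: float, slow: float) -> float:
        """Bilinear RPE depth at a fractional en-face position.

        Uses only valid neighbor columns; NaN if none of the four corners
        is valid.
        """
        f0 = int(np.clip(np.floor(fast), 0, self.geom.n_fast - 2))
        s0 = int(np.clip(np.floor(slow), 0, self.geom.n_slow - 2))
        df, ds = fast - f0, slow - s0
        w = np.array([(1 - df) * (1 - ds), (1 - df) * ds, df * (1 - ds), df * ds])
        z = np.array(
            [
                self.z_rpe[f0, s0],
                self.z_rpe[f0, s0 + 1],
                self.z_rpe[f0 + 1, s0],
                self.z_rpe[f0 + 1, s0 + 1],
            ]
        )
        ok = np.isfinite(z) & (w > 0)
        if not ok.any():
            ok = np.isfinite(z)
            if not ok.any():
                return float("nan")
        return float(np.sum(w[ok] * z[ok]) / np.sum(w[ok]))

    def radii_mm(self) -> np.ndarray:
        """Radial distance from the pivot to the RPE, per column (NaN invalid)."""
        return self.geom.radius_mm(self.z_rpe)

    def points3d(self) -> np.ndarray:
        """Physical RPE positions, shape (n_fast, n_slow, 3), NaN invalid."""
        if self._points_cache is None:
            dirs = self.geom.direction_grid()
            self._points_cache = dirs * self.radii_mm()[..., None]
        return self._points_cache

    def point_at(self, fast: float, slow: float) -> np.ndarray:
        """Physical RPE position at a fractional en-face index."""
        from .geometry import voxel_to_physical

        z = self.z_at(fast, slow)
        return voxel_to_physical((fast, slow, z), self.geom)


@dataclass
class ThicknessMap:
    """Retinal thickness per en-face column, mm; invalid where no retina."""

    thickness_mm: np.ndarray
    valid: np.ndarray
    geom: ScanGeometry


def _first_true(mask: np.ndarray) -> np.ndarray:
    """Index of the first True along the last axis (undefined where none)."""
    return mask.argmax(axis=-1)


def extract_rpe_surface(vol: LabelVolume) -> RpeSurface:
    """Locate the retina/choroid interface on every A-scan.

    For each column containing both labels, ``z_rpe`` is the first choroid
    index minus one half — the boundary between the last retina voxel and
    the first choroid voxel.  Columns lacking either tissue are invalid.

    Raises
    ------
    InvariantViolationError
        If any retina voxel occurs *after* the first choroid voxel on its
        ray, which violates the anatomical ordering of the labels.
    """
    v = vol.voxels
    ret = v == RETINA
    cho = v == CHOROID
    has_ret = ret.any(axis=-1)
    has_cho = cho.any(axis=-1)
    valid = has_ret & has_cho

    first_cho = _first_true(cho)
    last_ret = v.shape[-1] - 1 - _first_true(ret[..., ::-1])

    bad = valid & (last_ret > first_cho)
    if bad.any():
        f, s = np.argwhere(bad)[0]
        raise InvariantViolationError(
            f"retina occurs after choroid along column (fast={f}, slow={s})"
        )

    # retina runs per column: count rising edges of the retina mask
    rises = ret[..., 1:] & ~ret[..., :-1]
    n_runs = rises.sum(axis=-1) + ret[..., 0]
    n_multi = int(np.count_nonzero(valid & (n_runs > 1)))
    if n_multi:
        log.warning("%d columns have multiple retina runs; using the last "
                    "retina-to-choroid transition", n_multi)

    z = np.where(valid, first_cho - 0.5, np.nan)
    return RpeSurface(z_rpe=z, valid=valid, geom=vol.geom, n_multirun_columns=n_multi)


def thickness_map(vol: LabelVolume) -> ThicknessMap:
    """Retinal thickness = retina voxel count along the ray × depth step."""
    ret = vol.voxels == RETINA
    count = ret.sum(axis=-1)
    valid = count > 0
    return ThicknessMap(
        thickness_mm=count * vol.geom.depth_step_mm, valid=valid, geom=vol.geom
    )


def enface_projection(volume) -> np.ndarray:
    """En face maximum intensity projection: per-column max along depth.

    Accepts a :class:`LabelVolume` or any 3-D array ordered
    ``(fast, slow, depth)``.
    """
    v = volume.voxels if isinstance(volume, LabelVolume) else np.asarray(volume)
    return v.max(axis=-1)
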