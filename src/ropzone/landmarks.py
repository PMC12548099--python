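"""Landmark annotations, border chains, disc centroid and border sampling.

The three manual annotations are the optic-disc edge, the foveal center,
and the vascular–avascular border, all as en-face ``(fast, slow)`` points.
Sparse clicks are connected into contiguous pixel chains with integer
Bresenham rasterization, lifted to 3D via the RPE surface, and the border
is resampled at a fixed angular density about the disc center (10 points
per 30° clock hour by default) over the temporal hemisphere.

Bearings are measured in the en-face index plane, ``atan2(d_slow, d_fast)``
in degrees about the disc's en-face center, and unwrapped to the half-turn
window centered on the fovea's bearing.  The temporal hemisphere is the
half-plane, bounded by the line through the disc center perpendicular to
the disc→fovea direction, that contains the fovea; laterality only affects
clock-hour labeling, not the geometry.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnnotationError, FormatError, MeasurementError
from .geometry import ScanGeometry, physical_to_voxel, voxel_to_physical
from .surface import RpeSurface

__all__ = [
    "LandmarkSet",
    "BorderChain",
    "DiscCentroid",
    "SampledBorder",
    "bresenham_line",
    "bresenham_chain",
    "lift_to_surface",
    "build_border_chain",
    "disc_centroid_3d",
    "resample_border",
    "assessed_angle",
    "load_landmarks",
    "save_landmarks",
]

log = logging.getLogger(__name__)


@dataclass
class LandmarkSet:
    """Manual annotations for one eye, all 0-based (fast, slow) indices."""

    disc_edge: np.ndarray  # (N, 2)
    fovea: np.ndarray  # (2,)
    border_points: np.ndarray  # (M, 2)
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.disc_edge = np.atleast_2d(np.asarray(self.disc_edge, dtype=float))
        self.fovea = np.asarray(self.fovea, dtype=float).reshape(2)
        self.border_points = np.atleast_2d(np.asarray(self.border_points, dtype=float))
        if len(self.disc_edge) < 3:
            raise AnnotationError("need at least 3 disc-edge points")
        if len(self.border_points) < 2:
            raise AnnotationError("need at least 2 border points")
        if self.laterality not in ("OD", "OS"):
            raise AnnotationError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    def check_bounds(self, geom: ScanGeometry) -> None:
        """Raise AnnotationError naming the first out-of-grid point."""
        for name, pts in (
            ("disc_edge", self.disc_edge),
            ("fovea", self.fovea[None, :]),
            ("border", self.border_points),
        ):
            for i, (f, s) in enumerate(pts):
                if not (0 <= f <= geom.n_fast - 1 and 0 <= s <= geom.n_slow - 1):
                    raise AnnotationError(
                        f"{name} point {i} = ({f:g}, {s:g}) outside the "
                        f"{geom.n_fast}x{geom.n_slow} en-face grid"
                    )


@dataclass
class BorderChain:
    """Contiguous rasterized chain on the en-face grid, lifted to 3D."""

    cells: np.ndarray  # (N, 2) int
    points3d: np.ndarray  # (N, 3) mm
    n_interpolated: int = 0  # cells whose RPE depth came from neighbors


@dataclass
class DiscCentroid:
    """3D centroid of the optic-disc edge chain and its en-face projection."""

    position3d: np.ndarray  # (3,) mm
    enface_center: np.ndarray  # (2,) fractional (fast, slow)
    n_interpolated: int = 0


@dataclass
class SampledBorder:
    """Border resampled at fixed angular density about the disc center."""

    points3d: np.ndarray  # (M, 3)
    cells: np.ndarray  # (M, 2)
    bearings_deg: np.ndarray  # (M,) en-face bearings, fovea-centered unwrap
    covered_deg: float  # total temporal bearing coverage


# ---------------------------------------------------------------------------
# Bresenham rasterization


def bresenham_line(p0, p1) -> list[tuple[int, int]]:
    """Integer Bresenham segment from p0 to p1, inclusive of both ends."""
    x0, y0 = int(round(p0[0])), int(round(p0[1]))
    x1, y1 = int(round(p1[0])), int(round(p1[1]))
    dx, dy = abs(x1 - x0), -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    cells = []
    while True:
        cells.append((x0, y0))
        if x0 == x1 and y0 == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy
    return cells


def bresenham_chain(points, close: bool = False) -> np.ndarray:
    """Connect ordered annotation points into one 8-connected cell chain.

    Consecutive point pairs are rasterized with integer Bresenham and
    concatenated with duplicate junction cells removed; ``close=True``
    appends the segment back to the first point (for the disc-edge loop).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise AnnotationError("need at least 2 points to build a chain")
    seq = list(pts) + ([pts[0]] if close else [])
    cells: list[tuple[int, int]] = []
    for a, b in zip(seq[:-1], seq[1:]):
        seg = bresenham_line(a, b)
        if cells and seg and seg[0] == cells[-1]:
            seg = seg[1:]
        cells.extend(seg)
    if close and len(cells) > 1 and cells[-1] == cells[0]:
        cells = cells[:-1]
    return np.asarray(cells, dtype=int)


# ---------------------------------------------------------------------------
# Lifting chains onto the RPE surface


def lift_to_surface(
    cells: np.ndarray,
    surface: RpeSurface,
    geom: ScanGeometry,
    interp_radius: float = 5.0,
):
    """3D RPE positions for integer en-face cells.

    Cells on invalid columns borrow the RPE depth of the nearest valid
    column within ``interp_radius`` cells; beyond that a MeasurementError
    is raised.  Returns ``(points3d, n_interpolated)``.
    """
    cells = np.atleast_2d(np.asarray(cells, dtype=int))
    z = surface.z_rpe[cells[:, 0], cells[:, 1]]
    missing = ~np.isfinite(z)
    n_interp = int(missing.sum())
    if n_interp:
        valid_idx = np.argwhere(surface.valid)
        if len(valid_idx) == 0:
            raise MeasurementError("surface has no valid columns")
        tree = cKDTree(valid_idx)
        dist, nn = tree.query(cells[missing])
        if np.any(dist > interp_radius):
            bad = cells[missing][np.argmax(dist)]
            raise MeasurementError(
                f"no valid surface column within {interp_radius} cells of "
                f"(fast={bad[0]}, slow={bad[1]})"
            )
        z = z.copy()
        z[missing] = surface.z_rpe[valid_idx[nn, 0], valid_idx[nn, 1]]
        log.debug("interpolated RPE depth for %d chain cells", n_interp)
    idx = np.column_stack([cells.astype(float), z])
    return voxel_to_physical(idx, geom), n_interp


def build_border_chain(
    points,
    surface: RpeSurface,
    geom: ScanGeometry,
    interp_radius: float = 5.0,
) -> BorderChain:
    """Rasterize border annotation points and lift the chain to 3D."""
    cells = bresenham_chain(points)
    pts3d, n_interp = lift_to_surface(cells, surface, geom, interp_radius)
    return BorderChain(cells=cells, points3d=pts3d, n_interpolated=n_interp)


def disc_centroid_3d(
    disc_edge,
    surface: RpeSurface,
    geom: ScanGeometry,
    interp_radius: float = 5.0,
) -> DiscCentroid:
    """3D centroid of the closed disc-edge chain.

    The annotated edge points are connected into a closed Bresenham loop,
    each cell is lifted to the RPE (the disc interior itself may be an
    invalid region — edge cells on invalid columns borrow the nearest
    valid depth), and the centroid is the unweighted mean of the 3D chain
    points.  Its en-face center is the angular position of the mean,
    re-projected onto the index grid.
    """
    chain = bresenham_chain(disc_edge, close=True)
    pts3d, n_interp = lift_to_surface(chain, surface, geom, interp_radius)
    centroid = pts3d.mean(axis=0)
    enface = physical_to_voxel(centroid, geom)[:2]
    return DiscCentroid(position3d=centroid, enface_center=enface, n_interpolated=n_interp)


# ---------------------------------------------------------------------------
# Bearings, temporal hemisphere, resampling


def _enface_bearings(cells: np.ndarray, center: np.ndarray) -> np.ndarray:
    """En-face bearing (degrees) of each cell about ``center``."""
    d = np.asarray(cells, dtype=float) - np.asarray(center, dtype=float)
    return np.degrees(np.arctan2(d[:, 1], d[:, 0]))


def _unwrap_about(bearings: np.ndarray, ref: float) -> np.ndarray:
    """Map bearings into the half-turn window (ref-180, ref+180]."""
    return (bearings - ref + 180.0) % 360.0 - 180.0 + ref


def _temporal_selection(chain: BorderChain, disc: DiscCentroid, fovea):
    """Bearings of chain cells, unwrapped about the fovea bearing, plus the
    mask of cells in the temporal hemisphere (within 90° of the fovea)."""
    fovea = np.asarray(fovea, dtype=float)
    ref = float(_enface_bearings(fovea[None, :], disc.enface_center)[0])
    b = _unwrap_about(_enface_bearings(chain.cells, disc.enface_center), ref)
    temporal = np.abs(b - ref) <= 90.0
    return b, temporal, ref


def _as_chain_list(chain) -> list[BorderChain]:
    return list(chain) if isinstance(chain, (list, tuple)) else [chain]


def resample_border(
    chain,
    disc: DiscCentroid,
    fovea,
    density: int = 10,
    laterality: str = "OD",
) -> SampledBorder:
    """Resample the border at ``density`` evenly spaced points per clock hour.

    Sample bearings are laid out every ``30/density`` degrees from the
    start of each covered temporal bearing interval, half-open at the far
    end (a point at the interval end is excluded); each sample is the
    chain cell nearest in bearing.  ``chain`` may be a single
    :class:`BorderChain` or a list of chains (a border with gaps); coverage
    is then the union and sampling runs per contiguous chain.

    A chain lying entirely in the nasal hemisphere yields an empty result
    with a warning, not an error.
    """
    if density < 1:
        raise AnnotationError("density must be >= 1 point per clock hour")
    step = 30.0 / density
    all_pts, all_cells, all_bearings = [], [], []
    covered = 0.0
    for ch in _as_chain_list(chain):
        b, temporal, ref = _temporal_selection(ch, disc, fovea)
        if not temporal.any():
            continue
        bt = b[temporal]
        idx_t = np.flatnonzero(temporal)
        lo, hi = float(bt.min()), float(bt.max())
        covered += hi - lo
        targets = np.arange(lo, hi - 1e-9, step) if hi > lo else np.array([lo])
        for t in targets:
            j = idx_t[np.argmin(np.abs(bt - t))]
            all_pts.append(ch.points3d[j])
            all_cells.append(ch.cells[j])
            all_bearings.append(t)
    if not all_pts:
        warnings.warn("border chain lies entirely in the nasal hemisphere; "
                      "no samples taken", stacklevel=2)
        return SampledBorder(
            points3d=np.empty((0, 3)),
            cells=np.empty((0, 2), dtype=int),
            bearings_deg=np.empty(0),
            covered_deg=0.0,
        )
    return SampledBorder(
        points3d=np.asarray(all_pts),
        cells=np.asarray(all_cells),
        bearings_deg=np.asarray(all_bearings),
        covered_deg=min(covered, 180.0),
    )


def assessed_angle(chain, disc: DiscCentroid, fovea) -> float:
    """Angular extent (degrees) of covered temporal border, capped at 180.

    For a border with gaps (list of chains) the per-chain extents are
    summed (union of disjoint bearing intervals).
    """
    total = 0.0
    for ch in _as_chain_list(chain):
        b, temporal, _ = _temporal_selection(ch, disc, fovea)
        if temporal.any():
            bt = b[temporal]
            total += float(bt.max() - bt.min())
    return min(total, 180.0)


# ---------------------------------------------------------------------------
# JSON I/O


def load_landmarks(path) -> LandmarkSet:
    """Read a landmark annotation JSON document.

    Schema: ``{"disc_edge": [[fast, slow], ...], "fovea": [fast, slow],
    "border": [[fast, slow], ...], "laterality": "OD"|"OS"}``, indices
    0-based in (fast, slow) order.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse landmarks {path}: {exc}") from exc
    missing = {"disc_edge", "fovea", "border"} - set(doc)
    if missing:
        raise FormatError(f"landmarks {path} missing fields: {sorted(missing)}")
    try:
        return LandmarkSet(
            disc_edge=doc["disc_edge"],
            fovea=doc["fovea"],
            border_points=doc["border"],
            laterality=doc.get("laterality", "OD"),
        )
    except AnnotationError:
        raise
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed landmark data in {path}: {exc}") from exc


def save_landmarks(lm: LandmarkSet, path) -> None:
    doc = {
        "disc_edge": np.asarray(lm.disc_edge).tolist(),
        "fovea": np.asarray(lm.fovea).tolist(),
        "border": np.asarray(lm.border_points).tolist(),
        "laterality": lm.laterality,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
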