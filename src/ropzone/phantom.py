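"""Synthetic infant-eye phantoms with closed-form ground truth.

The phantom is an idealized globe: a sphere of radius ``R`` centered on
the scan pivot (the "central-pivot" geometry profile, ``al_scale = 2`` so
axial length is ``2R``).  Each ray is labeled retina over the radial
interval ``[R - t_ret, R)`` and choroid over ``[R, R + t_cho)``; the
retina thickens inside a band along the vascular–avascular border to
mimic the ROP ridge.  Because the pivot sits at the globe center, every
geodesic on the RPE is a great-circle arc and all ground truths are
closed-form: ``FD = R * theta_fovea`` and ``RAL(bearing) = R *
theta_border(bearing)``.

Landmarks are placed on the sphere in a disc-centered frame: the disc
pole sits ``disc_colatitude_deg`` off the scan axis (so border angular
radii up to ~90° stay inside a 140° field of view), the fovea lies
``fovea_offset_deg`` further along the temporal meridian, and the border
is a locus of angular radius ``theta_b(bearing)`` about the disc — a base
angle with an optional rectangular notch.  Annotations are emitted at the
exact grid projections of these loci, exactly as a clinician would click
them on the en face image.

The cohort generator emulates the eye-level structure of a screening
cohort — two eyes per patient sharing a patient-level random effect,
per-zone demographic and biomarker distributions, and a treatment outcome
whose risk falls with the retinal arclength — for exercising the
clustered statistics at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import ScanGeometry
from .landmarks import LandmarkSet
from .metrics import classify_zone_math, spherical_cap_avr, true_cap_area
from .surface import LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom_geometry",
    "generate_phantom",
    "generate_cohort",
    "COHORT_COLUMNS",
]


def make_phantom_geometry(
    n_fast: int = 400,
    n_slow: int = 400,
    n_depth: int = 110,
    fov_deg: float = 140.0,
    depth_step_mm: float = 0.02,
    pivot_offset_mm: float = 6.6,
) -> ScanGeometry:
    """Central-pivot scan geometry for phantoms.

    The depth window ``[6.6, 8.78] mm`` brackets globe radii 7–8.6 mm with
    retina and choroid shells included; ``al_scale = 2`` because the pivot
    is the globe center.
    """
    return ScanGeometry(
        n_fast=n_fast,
        n_slow=n_slow,
        n_depth=n_depth,
        fov_fast_deg=fov_deg,
        fov_slow_deg=fov_deg,
        depth_step_mm=depth_step_mm,
        pivot_offset_mm=pivot_offset_mm,
        al_scale=2.0,
        al_offset_mm=0.0,
    )


@dataclass
class PhantomSpec:
    """Configuration of one synthetic eye.

    Angles are degrees; the border profile is ``border_base_deg`` minus a
    raised-cosine notch of depth ``notch_depth_deg`` over the window
    ``|bearing - notch_center_deg| <= notch_width_deg / 2`` (bearing 0 is
    the temporal meridian through the fovea; the taper keeps the border a
    continuous curve, with the full depth attained at the window center).
    ``noise`` is the per-column probability that each tissue interface
    shifts by one voxel.
    """

    sphere_radius_mm: float = 7.7
    retina_thickness_mm: float = 0.20
    choroid_thickness_mm: float = 0.15
    disc_colatitude_deg: float = 25.0
    disc_angular_radius_deg: float = 4.0
    fovea_offset_deg: float = 28.3
    border_base_deg: float = 60.0
    border_span_deg: float = 70.0
    notch_center_deg: float = 0.0
    notch_width_deg: float = 20.0
    notch_depth_deg: float = 0.0
    ridge_thickening_mm: float = 0.10
    ridge_band_deg: float = 2.0
    noise: float = 0.0
    seed: int = 0
    n_disc_points: int = 12
    border_step_deg: float = 1.0
    sample_density: int = 10

    def __post_init__(self) -> None:
        if not 7.0 <= self.sphere_radius_mm <= 9.0:
            raise ConfigurationError("sphere radius must lie in [7, 9] mm (infant globe)")
        if min(self.retina_thickness_mm, self.choroid_thickness_mm) <= 0:
            raise ConfigurationError("tissue thicknesses must be positive")
        if self.fovea_offset_deg <= 0:
            raise ConfigurationError("fovea offset must be positive")
        lo = self.border_base_deg - self.notch_depth_deg
        if not 0.0 < lo <= self.border_base_deg < 180.0:
            raise ConfigurationError("border angular radii must lie in (0, 180) deg")
        if not 0.0 <= self.noise < 1.0:
            raise ConfigurationError("noise must lie in [0, 1)")

    @property
    def axial_length_mm(self) -> float:
        return 2.0 * self.sphere_radius_mm

    @property
    def disc_diameter_mm(self) -> float:
        """Disc diameter measured along the surface (arc)."""
        return 2.0 * self.sphere_radius_mm * np.deg2rad(self.disc_angular_radius_deg)

    def border_radius_deg(self, bearing_deg) -> np.ndarray:
        """Angular radius of the border locus at a (spherical) bearing."""
        b = np.asarray(bearing_deg, dtype=float)
        out = np.full_like(b, self.border_base_deg)
        if self.notch_depth_deg > 0:
            u = (b - self.notch_center_deg) / self.notch_width_deg  # +-0.5 window
            inside = np.abs(u) <= 0.5
            taper = 0.5 * (1.0 + np.cos(2.0 * np.pi * u))
            out = np.where(inside, self.border_base_deg - self.notch_depth_deg * taper, out)
        return out


@dataclass
class PhantomTruth:
    """Closed-form ground truth for one phantom."""

    sphere_radius_mm: float
    axial_length_mm: float
    fd_mm: float
    ral_bearings_deg: np.ndarray  # sampled en-face bearings about the disc
    ral_mm: np.ndarray
    mean_ral_mm: float
    min_ral_mm: float
    avr_mm2: float  # verbatim clinical cap formula at (mean RAL, AL)
    true_cap_area_mm2: float  # geometric cap area on the actual sphere
    zone: str
    disc_diameter_mm: float
    assessed_angle_enface_deg: float  # expected en-face bearing extent
    spec: PhantomSpec = field(repr=False)

    def ral_at(self, bearing_deg) -> np.ndarray:
        """True arclength R * theta_b at any bearing (mm)."""
        return self.sphere_radius_mm * np.deg2rad(self.spec.border_radius_deg(bearing_deg))


# ---------------------------------------------------------------------------
# disc-centered frame


def _disc_frame(spec: PhantomSpec):
    """Orthonormal frame at the disc pole: (pole, temporal tangent, binormal)."""
    th = np.deg2rad(spec.disc_colatitude_deg)
    d = np.array([-np.sin(th), 0.0, np.cos(th)])
    t = np.array([np.cos(th), 0.0, np.sin(th)])  # toward the fovea
    b = np.array([0.0, 1.0, 0.0])  # d x t
    return d, t, b


def _sphere_point(spec: PhantomSpec, theta_deg, bearing_deg) -> np.ndarray:
    """Unit direction at angular distance theta from the disc pole along a
    bearing measured from the temporal meridian."""
    d, t, b = _disc_frame(spec)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ga = np.deg2rad(np.asarray(bearing_deg, dtype=float))
    return (
        np.cos(th)[..., None] * d
        + np.sin(th)[..., None] * (np.cos(ga)[..., None] * t + np.sin(ga)[..., None] * b)
    )


def _direction_to_index(u: np.ndarray, geom: ScanGeometry, what: str) -> np.ndarray:
    """Exact fractional en-face index of unit directions; errors if outside FOV."""
    u = np.atleast_2d(u)
    alpha = np.arcsin(np.clip(u[:, 0], -1, 1))
    beta = np.arctan2(-u[:, 1], u[:, 2])
    fast, slow = geom.index_of_angles(alpha, beta)
    if (
        np.any(fast < 0) or np.any(fast > geom.n_fast - 1)
        or np.any(slow < 0) or np.any(slow > geom.n_slow - 1)
    ):
        raise ConfigurationError(f"phantom {what} falls outside the field of view")
    return np.column_stack([fast, slow])


def _truth_border_sampling(spec: PhantomSpec, geom: ScanGeometry):
    """Closed-form truth for the border sampling design.

    The measurement stage samples the border every ``30/density`` degrees
    of *en-face* bearing about the disc center, from the covered
    interval's start, half-open at the far end.  This reproduces that
    design analytically: the exact direction→index mapping takes the
    border locus to the en-face plane (the disc's en-face center is the
    projection of the 3D disc-ring centroid, which lies on the pole axis
    by symmetry), sample bearings are laid on the covered interval, and
    each is mapped back to its spherical bearing, where the arclength is
    ``R * theta_b``.  No pipeline object is involved.

    Returns ``(sample_bearings_enface_deg, sample_gamma_deg,
    assessed_angle_enface_deg)``.
    """
    d, _, _ = _disc_frame(spec)
    center = _direction_to_index(d, geom, "disc center")[0]
    fov_idx = _direction_to_index(
        _sphere_point(spec, spec.fovea_offset_deg, 0.0), geom, "fovea"
    )[0]
    half = spec.border_span_deg / 2.0
    gammas = np.arange(-half, half + 1e-9, 0.02)
    pts = _direction_to_index(
        _sphere_point(spec, spec.border_radius_deg(gammas), gammas), geom, "border"
    )
    ref = np.degrees(np.arctan2(fov_idx[1] - center[1], fov_idx[0] - center[0]))
    b = np.degrees(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
    b = (b - ref + 180.0) % 360.0 - 180.0
    keep = np.abs(b) <= 90.0
    b, gammas = b[keep], gammas[keep]
    assessed = float(min(b.max() - b.min(), 180.0)) if b.size else 0.0
    step = 30.0 / spec.sample_density
    targets = np.arange(b.min(), b.max() - 1e-9, step)
    order = np.argsort(b)
    sample_gamma = np.interp(targets, b[order], gammas[order])
    return targets, sample_gamma, assessed


# ---------------------------------------------------------------------------
# generation


def generate_phantom(spec: PhantomSpec, geom: ScanGeometry | None = None):
    """Build one synthetic eye: label volume, landmarks and ground truth.

    Deterministic for a given ``spec.seed``.  Returns
    ``(LabelVolume, LandmarkSet, PhantomTruth)``.
    """
    if geom is None:
        geom = make_phantom_geometry()
    R = spec.sphere_radius_mm
    po, step = geom.pivot_offset_mm, geom.depth_step_mm
    r_outer = R + spec.choroid_thickness_mm
    r_inner = R - spec.retina_thickness_mm - spec.ridge_thickening_mm
    if r_outer > po + (geom.n_depth - 1) * step or r_inner < po:
        raise ConfigurationError(
            f"globe [{r_inner:.2f}, {r_outer:.2f}] mm exceeds the scan depth "
            f"range [{po:.2f}, {po + (geom.n_depth - 1) * step:.2f}] mm"
        )

    rng = np.random.default_rng(spec.seed)
    d, t, b = _disc_frame(spec)
    dirs = geom.direction_grid()
    theta = np.degrees(np.arccos(np.clip(dirs @ d, -1.0, 1.0)))
    gamma = np.degrees(np.arctan2(dirs @ b, dirs @ t))

    t_ret = np.full(theta.shape, spec.retina_thickness_mm)
    if spec.ridge_thickening_mm > 0:
        on_ridge = (
            np.abs(theta - spec.border_radius_deg(gamma)) <= spec.ridge_band_deg
        ) & (np.abs(gamma) <= spec.border_span_deg / 2.0)
        t_ret = t_ret + spec.ridge_thickening_mm * on_ridge

    # integer depth-index boundaries of the three interfaces
    i0 = np.ceil((R - t_ret - po) / step).astype(np.int64)
    i1 = np.full_like(i0, int(np.ceil((R - po) / step)))
    i2 = np.full_like(i0, int(np.ceil((r_outer - po) / step)))
    if spec.noise > 0:
        for arr in (i0, i1, i2):
            flips = rng.random(arr.shape) < spec.noise
            arr += flips * rng.choice([-1, 1], size=arr.shape)
    i1 = np.maximum(i1, i0 + 1)  # keep at least one retina voxel
    i2 = np.maximum(i2, i1 + 1)

    ii = np.arange(geom.n_depth)
    voxels = np.zeros((geom.n_fast, geom.n_slow, geom.n_depth), dtype=np.uint8)
    voxels[(ii >= i0[..., None]) & (ii < i1[..., None])] = 1
    voxels[(ii >= i1[..., None]) & (ii < i2[..., None])] = 2
    vol = LabelVolume(voxels=voxels, geom=geom)

    # landmarks at exact grid projections of the configured loci
    disc_gammas = np.arange(spec.n_disc_points) * 360.0 / spec.n_disc_points
    disc_idx = _direction_to_index(
        _sphere_point(spec, np.full_like(disc_gammas, spec.disc_angular_radius_deg), disc_gammas),
        geom, "disc edge",
    )
    fovea_idx = _direction_to_index(
        _sphere_point(spec, spec.fovea_offset_deg, 0.0), geom, "fovea"
    )[0]
    half = spec.border_span_deg / 2.0
    bg = np.arange(-half, half + 1e-9, spec.border_step_deg)
    border_idx = _direction_to_index(
        _sphere_point(spec, spec.border_radius_deg(bg), bg), geom, "border"
    )
    landmarks = LandmarkSet(
        disc_edge=disc_idx,
        fovea=fovea_idx,
        border_points=border_idx,
        laterality="OD",
    )

    # closed-form truth
    bearings, sample_gamma, assessed_enface = _truth_border_sampling(spec, geom)
    ral = R * np.deg2rad(spec.border_radius_deg(sample_gamma))
    fd = R * np.deg2rad(spec.fovea_offset_deg)
    mean_ral, min_ral = float(ral.mean()), float(ral.min())
    zone = classify_zone_math(min_ral, fd, spec.disc_diameter_mm).label
    truth = PhantomTruth(
        sphere_radius_mm=R,
        axial_length_mm=spec.axial_length_mm,
        fd_mm=fd,
        ral_bearings_deg=bearings,
        ral_mm=ral,
        mean_ral_mm=mean_ral,
        min_ral_mm=min_ral,
        avr_mm2=spherical_cap_avr(mean_ral, spec.axial_length_mm),
        true_cap_area_mm2=true_cap_area(R, mean_ral),
        zone=zone,
        disc_diameter_mm=spec.disc_diameter_mm,
        assessed_angle_enface_deg=assessed_enface,
        spec=spec,
    )
    return vol, landmarks, truth


# ---------------------------------------------------------------------------
# cohort simulation

COHORT_COLUMNS = [
    "patient_id", "eye", "zone", "ga_weeks", "bw_g", "pma_weeks",
    "mean_ral_mm", "min_ral_mm", "avr_mm2", "zone_ratio", "treated",
]

#: Per-zone generative defaults (zone I, posterior zone II, zone II):
#: (mean, sd) of each eye- or patient-level quantity in a screening cohort.
DEFAULT_EFFECTS = {
    "zone_mix": (18 / 52, 5 / 52, 29 / 52),
    "ga_weeks": ((24.1, 1.2), (24.2, 1.0), (27.8, 2.1)),
    "bw_g": ((557.9, 116.8), (605.0, 84.4), (964.6, 414.7)),
    "pma_weeks": ((33.3, 1.5), (32.6, 1.5), (35.9, 3.1)),
    "al_mm": ((15.4, 0.5), (15.2, 0.6), (16.0, 0.6)),
    "fd_mm": ((4.5, 0.5), (4.8, 0.6), (4.7, 0.6)),
    "mean_ral_mm": ((10.3, 1.2), (11.9, 1.4), (14.8, 1.1)),
    "min_offset_mm": ((1.5, 0.3), (1.5, 0.3), (1.2, 0.3)),
    "inter_eye_rho": 0.8,
    "treat_intercept": 10.2,
    "treat_slope": -0.95,
}

_ZONES = ("I", "PII", "II")


def generate_cohort(
    n_patients: int,
    zone_mix=None,
    effect_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an eye-level cohort table (two eyes per patient).

    Each patient draws a latent severity from a standard normal; zone is
    assigned by severity thresholds matching ``zone_mix`` (lower latent
    value = more posterior disease).  Demographics are patient-level
    per-zone normals; the per-eye mean arclength shares a patient random
    effect with intra-class correlation ``inter_eye_rho``; min-RAL is the
    mean minus a positive offset; treatment is Bernoulli in a logistic
    model decreasing in mean-RAL.  Deterministic for a given seed.
    """
    if n_patients < 2:
        raise ConfigurationError("need at least 2 patients")
    eff = dict(DEFAULT_EFFECTS)
    if effect_params:
        unknown = set(effect_params) - set(eff)
        if unknown:
            raise ConfigurationError(f"unknown effect parameters: {sorted(unknown)}")
        eff.update(effect_params)
    mix = np.asarray(zone_mix if zone_mix is not None else eff["zone_mix"], dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ConfigurationError("zone_mix must be 3 non-negative probabilities summing to 1")

    from scipy.special import expit
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    severity = rng.standard_normal(n_patients)
    cuts = norm.ppf(np.clip(np.cumsum(mix)[:2], 1e-12, 1 - 1e-12))
    zone_idx = np.digitize(severity, cuts)  # 0=I, 1=PII, 2=II

    rho = float(eff["inter_eye_rho"])
    rows = []
    for pid in range(n_patients):
        zi = int(zone_idx[pid])
        ga = rng.normal(*eff["ga_weeks"][zi])
        bw = rng.normal(*eff["bw_g"][zi])
        pma = rng.normal(*eff["pma_weeks"][zi])
        m_ral, s_ral = eff["mean_ral_mm"][zi]
        patient_eff = rng.normal(0.0, np.sqrt(rho) * s_ral)
        for eye in ("OD", "OS"):
            mean_ral = m_ral + patient_eff + rng.normal(0.0, np.sqrt(1 - rho) * s_ral)
            mean_ral = max(mean_ral, 1.0)
            offset = max(rng.normal(*eff["min_offset_mm"][zi]), 0.1)
            min_ral = max(mean_ral - offset, 0.5)
            al = max(rng.normal(*eff["al_mm"][zi]), 10.0)
            fd = max(rng.normal(*eff["fd_mm"][zi]), 3.0)
            p_treat = expit(eff["treat_intercept"] + eff["treat_slope"] * mean_ral)
            rows.append({
                "patient_id": f"P{pid:05d}",
                "eye": eye,
                "zone": _ZONES[zi],
                "ga_weeks": ga,
                "bw_g": bw,
                "pma_weeks": pma,
                "mean_ral_mm": mean_ral,
                "min_ral_mm": min_ral,
                "avr_mm2": spherical_cap_avr(mean_ral, al),
                "zone_ratio": min_ral / fd,
                "treated": int(rng.random() < p_treat),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
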