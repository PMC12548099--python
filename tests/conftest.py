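import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ropzone import (
    PhantomSpec,
    RpeSurface,
    RunConfig,
    ScanGeometry,
    generate_phantom,
    make_phantom_geometry,
    measure_eye,
)

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("repro")


def make_sphere_surface(R: float = 7.7, n: int = 200, fov: float = 140.0):
    """Analytic spherical RPE surface (pivot at the globe center).

    Every ray hits the sphere at the same radius, so the surface is a
    constant depth field; geodesic truths are great-circle arcs.
    """
    geom = ScanGeometry(
        n_fast=n, n_slow=n, n_depth=2,
        fov_fast_deg=fov, fov_slow_deg=fov,
        depth_step_mm=0.02, pivot_offset_mm=R - 0.02, al_scale=2.0,
    )
    z = np.ones((n, n))
    surf = RpeSurface(z_rpe=z, valid=np.ones((n, n), bool), geom=geom)
    return surf, geom


@pytest.fixture()
def sphere_surface():
    return make_sphere_surface


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default phantom generated once and measured end to end."""
    geom = make_phantom_geometry(n_fast=160, n_slow=160)
    spec = PhantomSpec()
    vol, lm, truth = generate_phantom(spec, geom)
    res = measure_eye(vol, lm, RunConfig(disc_diameter_mm=truth.disc_diameter_mm))
    return vol, lm, truth, res
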