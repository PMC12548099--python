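"""Bresenham chains, disc centroid, border resampling, assessed angle."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.draw import line as skimage_line

from ropzone import (
    BorderChain,
    DiscCentroid,
    LandmarkSet,
    assessed_angle,
    bresenham_chain,
    bresenham_line,
    disc_centroid_3d,
    load_landmarks,
    resample_border,
    save_landmarks,
    voxel_to_physical,
)
from ropzone.errors import AnnotationError, FormatError
from ropzone.landmarks import lift_to_surface

from conftest import make_sphere_surface

coords = st.integers(-40, 40)


class TestBresenham:
    def test_axis_aligned_segment(self):
        assert bresenham_line((0, 0), (0, 5)) == [(0, k) for k in range(6)]

    @given(x0=coords, y0=coords, x1=coords, y1=coords)
    def test_matches_reference_rasterizer(self, x0, y0, x1, y1):
        ours = bresenham_line((x0, y0), (x1, y1))
        rr, cc = skimage_line(x0, y0, x1, y1)
        assert ours == list(zip(rr.tolist(), cc.tolist()))

    @given(x0=coords, y0=coords, x1=coords, y1=coords)
    def test_segment_length_bounds(self, x0, y0, x1, y1):
        n = len(bresenham_line((x0, y0), (x1, y1)))
        dfast, dslow = abs(x1 - x0), abs(y1 - y0)
        assert max(dfast, dslow) + 1 <= n <= dfast + dslow + 1

    def test_chain_is_8_connected_and_visits_inputs(self):
        pts = [(0, 0), (4, 2), (9, -3), (9, 10)]
        cells = bresenham_chain(pts)
        steps = np.abs(np.diff(cells, axis=0)).max(axis=1)
        assert (steps == 1).all()
        for p in pts:
            assert (cells == p).all(axis=1).any()

    def test_closed_loop_ends_adjacent(self):
        cells = bresenham_chain([(0, 0), (10, 0), (10, 10), (0, 10)], close=True)
        assert np.abs(cells[0] - cells[-1]).max() <= 1

    def test_single_point_rejected(self):
        with pytest.raises(AnnotationError):
            bresenham_chain([(0, 0)])


class TestDiscCentroid:
    def test_ring_about_pole_lands_on_axis(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=200)
        c = (geom.n_fast - 1) / 2.0
        # 12 points on a 3-degree circle about the central axis
        ang = np.deg2rad(3.0)
        cells_per_deg = (geom.n_fast - 1) / geom.fov_fast_deg
        bearings = np.deg2rad(np.arange(12) * 30.0)
        pts = np.column_stack([
            c + np.degrees(ang) * cells_per_deg * np.cos(bearings),
            c + np.degrees(ang) * cells_per_deg * np.sin(bearings),
        ])
        disc = disc_centroid_3d(pts, surf, geom)
        assert np.hypot(disc.position3d[0], disc.position3d[1]) < 0.05
        np.testing.assert_allclose(disc.enface_center, [c, c], atol=0.5)

    def test_cyclic_rotation_invariance(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=120)
        pts = np.array([(60, 50), (70, 63), (55, 70), (48, 58)])
        a = disc_centroid_3d(pts, surf, geom)
        b = disc_centroid_3d(np.roll(pts, 2, axis=0), surf, geom)
        np.testing.assert_allclose(a.position3d, b.position3d, atol=1e-12)

    def test_constant_depth_chain_lifts_to_constant_radius(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=120)
        cells = bresenham_chain([(40, 40), (60, 45), (50, 60)], close=True)
        pts, n_interp = lift_to_surface(cells, surf, geom)
        assert n_interp == 0
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 7.7, atol=1e-9)

    def test_invalid_columns_interpolated_within_radius(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=120)
        surf.valid[58:63, 58:63] = False
        surf.z_rpe[58:63, 58:63] = np.nan
        cells = np.array([(60, 60), (60, 70)])
        pts, n_interp = lift_to_surface(cells, surf, geom, interp_radius=5)
        assert n_interp == 1
        assert np.all(np.isfinite(pts))


def circle_chain(surf, geom, center, radius_cells, b0, b1, n=400):
    """Synthetic border chain on integer cells along a bearing arc."""
    bearings = np.deg2rad(np.linspace(b0, b1, n))
    cells = np.unique(
        np.rint(np.column_stack([
            center[0] + radius_cells * np.cos(bearings),
            center[1] + radius_cells * np.sin(bearings),
        ])).astype(int), axis=0,
    )
    pts, _ = lift_to_surface(cells, surf, geom)
    return BorderChain(cells=cells, points3d=pts)


class TestResampleBorder:
    @pytest.fixture()
    def scene(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=200)
        center = np.array([99.5, 99.5])
        disc = DiscCentroid(
            position3d=voxel_to_physical((99.5, 99.5, 1.0), geom),
            enface_center=center,
        )
        fovea = np.array([160.0, 99.5])  # bearing 0 from the disc
        return surf, geom, disc, fovea

    def test_two_clock_hours_give_twenty_samples(self, scene):
        surf, geom, disc, fovea = scene
        chain = circle_chain(surf, geom, disc.enface_center, 70, -30, 30)
        sampled = resample_border(chain, disc, fovea, density=10)
        assert abs(len(sampled.points3d) - 20) <= 1
        assert abs(sampled.covered_deg - 60.0) < 2.0

    @pytest.mark.parametrize("b0,b1,density", [(-30, 30, 10), (-15, 15, 10), (-30, 30, 5)])
    def test_count_matches_coverage_rule(self, scene, b0, b1, density):
        surf, geom, disc, fovea = scene
        chain = circle_chain(surf, geom, disc.enface_center, 70, b0, b1)
        sampled = resample_border(chain, disc, fovea, density=density)
        step = 30.0 / density
        expect = int(np.floor(sampled.covered_deg / step))
        assert abs(len(sampled.points3d) - expect) <= 1
        # full clock-hour arcs: ~10 points per 30 degrees
        assert abs(len(sampled.points3d) - (b1 - b0) / step) <= 1

    def test_constant_radius_gives_equidistant_samples(self, scene):
        surf, geom, disc, fovea = scene
        chain = circle_chain(surf, geom, disc.enface_center, 70, -35, 35)
        sampled = resample_border(chain, disc, fovea)
        d = np.linalg.norm(sampled.points3d - disc.position3d, axis=1)
        assert np.ptp(d) <= np.linalg.norm(
            voxel_to_physical((0, 0, 1), geom) - voxel_to_physical((1, 1, 1), geom)
        ) * 2  # within a couple of cells of quantization

    def test_nasal_chain_warns_and_returns_empty(self, scene):
        surf, geom, disc, fovea = scene
        chain = circle_chain(surf, geom, disc.enface_center, 70, 150, 210)
        with pytest.warns(UserWarning, match="nasal"):
            sampled = resample_border(chain, disc, fovea)
        assert len(sampled.points3d) == 0

    def test_gap_border_union_coverage(self, scene):
        surf, geom, disc, fovea = scene
        chains = [
            circle_chain(surf, geom, disc.enface_center, 70, -40, -10),
            circle_chain(surf, geom, disc.enface_center, 70, 10, 40),
        ]
        sampled = resample_border(chains, disc, fovea)
        total = assessed_angle(chains, disc, fovea)
        assert 55 <= total <= 65  # two ~30-degree intervals
        assert abs(len(sampled.points3d) - total / 3.0) <= 2


class TestAssessedAngle:
    def test_symmetric_span(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=200)
        center = np.array([99.5, 99.5])
        disc = DiscCentroid(
            position3d=voxel_to_physical((99.5, 99.5, 1.0), geom),
            enface_center=center,
        )
        fovea = np.array([160.0, 99.5])
        chain = circle_chain(surf, geom, center, 70, -35, 35)
        angle = assessed_angle(chain, disc, fovea)
        assert abs(angle - 70.0) < 2.0

    def test_full_coverage_caps_at_180(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=200)
        center = np.array([99.5, 99.5])
        disc = DiscCentroid(
            position3d=voxel_to_physical((99.5, 99.5, 1.0), geom),
            enface_center=center,
        )
        fovea = np.array([160.0, 99.5])
        chain = circle_chain(surf, geom, center, 70, -120, 120)
        # the temporal hemisphere is a 180-degree window; cell quantization
        # can shave a fraction of a degree off the discrete extent
        assert 178.0 <= assessed_angle(chain, disc, fovea) <= 180.0

    def test_matches_brute_force_extent(self, sphere_surface):
        surf, geom = sphere_surface(R=7.7, n=200)
        center = np.array([99.5, 99.5])
        disc = DiscCentroid(
            position3d=voxel_to_physical((99.5, 99.5, 1.0), geom),
            enface_center=center,
        )
        fovea = np.array([160.0, 99.5])
        rng = np.random.default_rng(3)
        b0 = rng.uniform(-80, 0)
        chain = circle_chain(surf, geom, center, 65, b0, b0 + rng.uniform(10, 80))
        # brute force: scan every cell's bearing
        d = chain.cells - center
        bearings = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        keep = np.abs(bearings) <= 90
        expect = bearings[keep].max() - bearings[keep].min()
        assert np.isclose(assessed_angle(chain, disc, fovea), expect, atol=1e-9)


class TestLandmarkIO:
    def test_round_trip(self, tmp_path):
        lm = LandmarkSet(
            disc_edge=[[10, 10], [12, 14], [8, 13]],
            fovea=[40, 20],
            border_points=[[60, 5], [62, 30], [58, 55]],
            laterality="OS",
        )
        save_landmarks(lm, tmp_path / "lm.json")
        back = load_landmarks(tmp_path / "lm.json")
        np.testing.assert_array_equal(back.disc_edge, lm.disc_edge)
        np.testing.assert_array_equal(back.fovea, lm.fovea)
        np.testing.assert_array_equal(back.border_points, lm.border_points)
        assert back.laterality == "OS"

    def test_missing_field_is_format_error(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"fovea": [1, 2]}))
        with pytest.raises(FormatError, match="disc_edge"):
            load_landmarks(tmp_path / "bad.json")

    def test_too_few_points_rejected(self):
        with pytest.raises(AnnotationError, match="disc-edge"):
            LandmarkSet(disc_edge=[[0, 0], [1, 1]], fovea=[5, 5],
                        border_points=[[9, 9], [9, 8]])

    def test_out_of_grid_point_named(self, sphere_surface):
        _, geom = sphere_surface(n=50)
        lm = LandmarkSet(
            disc_edge=[[10, 10], [12, 14], [8, 13]],
            fovea=[40, 20],
            border_points=[[60, 5], [45, 30]],
        )
        with pytest.raises(AnnotationError, match="border point 0"):
            lm.check_bounds(geom)
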