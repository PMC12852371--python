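"""Geometric primitives: centerlines, junctions, cross-sections, ostial planes."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from atriometry import (
    LabelMap,
    OstiumNotFoundError,
    equivalent_diameter,
    establish_axes,
    extract_centerline,
    find_junction_point,
    find_ostial_plane,
    ostial_direction,
    planar_cross_section,
)
from atriometry.geometry import AxesFrame, OstialPlane
from atriometry.labelmap import postprocess_labels, resample_isotropic
from atriometry.phantom import LaaSpec, PhantomSpec, TubeSpec, generate_phantom


def single_tube_map(radius=6.0, direction=(1.0, 0.0, 0.0), length=30.0, **tube_kw):
    spec = PhantomSpec(
        pv={"lspv": TubeSpec(radius=radius, direction=direction, length=length, **tube_kw)},
        laa=LaaSpec(present=False),
    )
    lm, gt = generate_phantom(spec)
    return postprocess_labels(resample_isotropic(lm, 0.5)), spec


def curve_tube_map(curve_points, tube_radius=4.0, sphere_radius=15.0, spacing=0.5):
    """Sphere LA (label 1) plus a flat-capped tube around a polyline (label 3)."""
    pts = np.asarray(curve_points)
    lo = np.minimum(pts.min(axis=0) - tube_radius, -sphere_radius) - 3
    hi = np.maximum(pts.max(axis=0) + tube_radius, sphere_radius) + 3
    origin = (np.floor(lo / spacing) - 0.5) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1
    ax = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    dist = cKDTree(pts).query(grid)[0].reshape(tuple(shape))
    t0 = pts[1] - pts[0]
    t0 /= np.linalg.norm(t0)
    t1 = pts[-1] - pts[-2]
    t1 /= np.linalg.norm(t1)
    inside_caps = (
        ((grid - pts[0]) @ t0 >= 0) & ((grid - pts[-1]) @ t1 <= 0)
    ).reshape(tuple(shape))
    r2 = gx**2 + gy**2 + gz**2
    vox = np.zeros(tuple(shape), dtype=np.int16)
    vox[r2 <= sphere_radius**2] = 1
    vox[(dist <= tube_radius) & inside_caps & (r2 > sphere_radius**2)] = 3
    return LabelMap(vox, spacing=[spacing] * 3, origin=origin)


class TestCenterline:
    def test_straight_cylinder_on_axis(self):
        lm, spec = single_tube_map()
        cl = extract_centerline(lm, "lspv")
        ax = spec.attachment_axis(spec.pv["lspv"])
        pa = spec.attachment_point(spec.pv["lspv"])
        rel = cl.points - pa
        off_axis = np.linalg.norm(rel - (rel @ ax)[:, None] * ax, axis=1)
        assert off_axis.max() < 0.5  # within 1 voxel of the true axis

    def test_contract_spacing_and_arclength(self):
        lm, _ = single_tube_map()
        cl = extract_centerline(lm, "lspv")
        steps = np.diff(cl.arclength)
        assert np.all(steps > 0)
        assert steps.max() <= 1.0 + 1e-9

    def test_endpoints_near_junction_and_tip(self):
        lm, spec = single_tube_map()
        cl = extract_centerline(lm, "lspv")
        pa = spec.attachment_point(spec.pv["lspv"])
        ax = spec.attachment_axis(spec.pv["lspv"])
        assert np.linalg.norm(cl.points[0] - pa) < 1.0  # 2 voxels of interface
        tip = pa + spec.pv["lspv"].length * ax
        assert np.linalg.norm(cl.points[-1] - tip) < 1.5

    def test_bent_tube_arc_length(self):
        # quarter-torus: ring radius 20 mm from the sphere surface, arc 10*pi
        u = np.linspace(0, np.pi / 2, 200)
        center = np.array([15.0, 0.0, 20.0])
        curve = center + 20.0 * np.column_stack(
            [np.sin(u), np.zeros_like(u), -np.cos(u)]
        )
        lm = curve_tube_map(curve)
        cl = extract_centerline(lm, "lspv")
        expected = 20.0 * np.pi / 2
        assert abs(cl.length - expected) / expected < 0.05

    def test_empty_structure_raises(self):
        lm, _ = single_tube_map()
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(lm, "ripv")


class TestJunction:
    def test_port_center_recovered(self):
        lm, spec = single_tube_map()
        j = find_junction_point(lm, "lspv")
        pa = spec.attachment_point(spec.pv["lspv"])
        assert np.linalg.norm(j - pa) < 0.5

    def test_no_adjacency_raises(self):
        vox = np.zeros((20, 10, 10), dtype=np.int16)
        vox[0:4, 2:8, 2:8] = 1
        vox[10:14, 2:8, 2:8] = 3  # far from the LA block
        lm = LabelMap(vox, spacing=[0.5] * 3)
        with pytest.raises(ValueError, match="adjacency"):
            find_junction_point(lm, "lspv")

    def test_two_patches_uses_larger_and_flags(self):
        # U-shaped structure touching the LA slab at two separate feet
        vox = np.zeros((24, 12, 14), dtype=np.int16)
        vox[:, :, 0:4] = 1  # LA slab
        vox[2:6, 4:8, 4:8] = 3  # small foot
        vox[12:22, 4:8, 4:8] = 3  # large foot
        vox[2:22, 4:8, 8:12] = 3  # bridge, away from the LA
        lm = LabelMap(vox, spacing=[0.5] * 3)
        flags = []
        j = find_junction_point(lm, "lspv", flags=flags)
        assert any("multiple_patches" in f for f in flags)
        # centroid of the larger foot, x in [12, 22) voxels
        assert 12 * 0.5 <= (j[0] - lm.origin[0]) <= 22 * 0.5


class TestCrossSection:
    def test_perpendicular_disc_area(self):
        lm, spec = single_tube_map()
        ax = spec.attachment_axis(spec.pv["lspv"])
        center = spec.attachment_point(spec.pv["lspv"]) + 15.0 * ax
        area = planar_cross_section(lm, center, ax, {"lspv"})
        assert abs(area - np.pi * 36.0) / (np.pi * 36.0) < 0.03

    def test_background_plane_is_zero(self, default_iso_map):
        area = planar_cross_section(
            default_iso_map, np.array([200.0, 200.0, 200.0]), np.array([0, 0, 1.0]),
            {"la"},
        )
        assert area == 0.0

    def test_oblique_section_ellipse_area(self):
        lm, spec = single_tube_map()
        ax = spec.attachment_axis(spec.pv["lspv"])
        center = spec.attachment_point(spec.pv["lspv"]) + 15.0 * ax
        # normal at 60 degrees to the tube axis -> area pi r^2 / cos(60)
        perp = np.cross(ax, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        normal = np.cos(np.radians(60)) * ax + np.sin(np.radians(60)) * perp
        area = planar_cross_section(lm, center, normal, {"lspv"})
        expected = np.pi * 36.0 / np.cos(np.radians(60))
        assert abs(area - expected) / expected < 0.05

    def test_zero_normal_rejected(self, default_iso_map):
        with pytest.raises(ValueError):
            planar_cross_section(default_iso_map, np.zeros(3), np.zeros(3), {"la"})


class TestOstialPlane:
    @pytest.mark.parametrize("radius", [4.0, 6.0, 8.0, 10.0])
    def test_uniform_tube_equivalent_diameter(self, radius):
        lm, _ = single_tube_map(radius=radius)
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        assert abs(plane.equivalent_diameter - 2 * radius) / (2 * radius) < 0.05
        assert abs(plane.junction_offset) <= 5.0

    def test_waisted_tube_selects_waist(self):
        tilt = np.radians(15)
        lm, _ = single_tube_map(
            axis=(np.cos(tilt), 0.0, np.sin(tilt)), waist_radius=5.0, waist_offset=2.0
        )
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        assert abs(plane.equivalent_diameter - 10.0) / 10.0 < 0.05

    def test_agrees_with_dense_axis_search(self):
        # exhaustive minimal area over densely stepped on-axis planes
        lm, spec = single_tube_map()
        ax = spec.attachment_axis(spec.pv["lspv"])
        pa = spec.attachment_point(spec.pv["lspv"])
        dense = []
        for s in np.arange(0.0, 5.0, 0.1):
            a = planar_cross_section(lm, pa + s * ax, ax, {"lspv", "la"})
            if a > 0:
                dense.append(a)
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        d_dense = equivalent_diameter(min(dense))
        assert abs(plane.equivalent_diameter - d_dense) / d_dense < 0.05

    def test_detached_structure_raises(self):
        vox = np.zeros((30, 14, 14), dtype=np.int16)
        vox[0:5, :, :] = 1
        vox[10:28, 4:10, 4:10] = 3
        lm = LabelMap(vox, spacing=[0.5] * 3)
        with pytest.raises(ValueError):
            extract_centerline(lm, "lspv")

    def test_invariants(self, default_iso_map):
        cl = extract_centerline(default_iso_map, "lspv")
        plane = find_ostial_plane(default_iso_map, "lspv", cl)
        assert abs(np.linalg.norm(plane.normal) - 1) < 1e-9
        assert abs(plane.equivalent_diameter - 2 * np.sqrt(plane.area / np.pi)) < 1e-9


class TestOstialDirection:
    @pytest.mark.parametrize("spacing", [0.4, 0.8])
    def test_straight_tube_direction(self, spacing):
        spec = PhantomSpec(
            pv={"lspv": TubeSpec()}, laa=LaaSpec(present=False),
            voxel_spacing=(spacing,) * 3,
        )
        lm, _ = generate_phantom(spec)
        lm = postprocess_labels(resample_isotropic(lm, 0.5))
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        v = ostial_direction(cl, plane)
        ax = spec.attachment_axis(spec.pv["lspv"])
        assert np.degrees(np.arccos(np.clip(v @ ax, -1, 1))) < 1.0

    def test_bend_beyond_window_uses_window_chord(self):
        # straight for 14 mm, then a bend: the reported direction follows the
        # straight ostial segment, not the distal tangent
        s1 = np.linspace(0, 14, 60)
        straight = np.column_stack([15.0 + s1, np.zeros_like(s1), np.zeros_like(s1)])
        u = np.linspace(0, np.pi / 2, 120)
        bend = np.column_stack(
            [29.0 + 15.0 * np.sin(u), np.zeros_like(u), 15.0 * (1 - np.cos(u))]
        )
        lm = curve_tube_map(np.vstack([straight, bend]))
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        v = ostial_direction(cl, plane)
        angle_to_axis = np.degrees(np.arccos(np.clip(v @ np.array([1.0, 0, 0]), -1, 1)))
        distal_tangent = cl.tangent_at(cl.length - 1.0)
        angle_distal = np.degrees(
            np.arccos(np.clip(distal_tangent @ np.array([1.0, 0, 0]), -1, 1))
        )
        assert angle_to_axis < 5.0
        assert angle_distal > 30.0

    def test_short_stub_raises(self):
        lm, _ = single_tube_map(length=12.0)
        cl = extract_centerline(lm, "lspv")
        plane = find_ostial_plane(lm, "lspv", cl)
        with pytest.raises(ValueError, match="distal"):
            ostial_direction(cl, plane, arm=15.0)


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "area,expected", [(np.pi, 2.0), (0.0, 0.0), (113.097, 12.0)]
    )
    def test_closed_form(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("d", [5.0, 12.0, 30.0])
    def test_disc_roundtrip(self, d):
        assert equivalent_diameter(np.pi * d * d / 4.0) == pytest.approx(d, abs=1e-9)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(-1.0)


class TestAxes:
    def test_default_image_axes(self, default_iso_map):
        frame = establish_axes(default_iso_map)
        assert frame.source == "image-axes"
        assert np.allclose(frame.ml, [1, 0, 0])
        assert np.allclose(frame.ap, [0, 1, 0])
        assert np.allclose(frame.si, [0, 0, 1])

    def test_tilted_annulus_ring(self, default_iso_map):
        # ring tilted 20 degrees about the ML axis
        t = np.radians(20)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
        )
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        ring = np.column_stack(
            [15 * np.cos(theta), 15 * np.sin(theta), np.full_like(theta, -24.0)]
        ) @ rot.T
        frame = establish_axes(default_iso_map, annulus_points=ring)
        tilt = np.degrees(np.arccos(np.clip(frame.si @ np.array([0, 0, 1.0]), -1, 1)))
        assert abs(tilt - 20.0) < 1.0
        assert frame.source == "annulus-plane"

    def test_collinear_points_rejected(self, default_iso_map):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            establish_axes(default_iso_map, annulus_points=pts)

    def test_frame_orthonormal_right_handed(self, default_iso_map):
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [20 * np.cos(np.linspace(0, 6, 9)), 20 * np.sin(np.linspace(0, 6, 9)),
             rng.normal(-22, 0.3, 9)]
        )
        f = establish_axes(default_iso_map, annulus_points=pts)
        m = np.column_stack([f.ml, f.ap, f.si])
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-9)
        assert np.linalg.det(m) > 0


class TestEquivalentDiameterProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_roundtrip_and_monotonicity(self, area):
        d = equivalent_diameter(area)
        assert np.pi * d * d / 4.0 == pytest.approx(area, rel=1e-12, abs=1e-12)
        assert equivalent_diameter(area + 1.0) > d
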