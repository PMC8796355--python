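"""Plane algebra, rigid transforms, and mesh membership/distance queries."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from cupcov.geometry import (
    DegenerateGeometryError,
    MeshQueries,
    NotWatertightError,
    Plane,
    RigidTransform,
    plane_from_points,
    point_in_solid,
    point_plane_distance,
    surface_area,
)


def unit_cube():
    cube = trimesh.creation.box(extents=[1, 1, 1])
    cube.apply_translation([0.5, 0.5, 0.5])
    return cube


class TestPlane:
    @pytest.mark.parametrize(
        "p, q, r, orient, expected",
        [
            ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, 1, 0)),
            ((5, 0, 0), (5, 1, 0), (5, 0, 1), (9, 0, 0), (1, 0, 0, -5)),
        ],
    )
    def test_canonical_planes(self, p, q, r, orient, expected):
        plane = plane_from_points(p, q, r, orient_toward=orient)
        assert np.allclose((plane.a, plane.b, plane.c, plane.d), expected)

    def test_three_points_satisfy_equation(self, rng):
        for _ in range(20):
            pts = rng.normal(scale=40, size=(3, 3))
            try:
                plane = plane_from_points(*pts)
            except DegenerateGeometryError:
                continue
            assert np.all(np.abs(plane.signed_distance(pts)) < 1e-9)
            # normal equals the normalized edge cross product (up to sign)
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            n /= np.linalg.norm(n)
            assert min(
                np.linalg.norm(plane.normal - n), np.linalg.norm(plane.normal + n)
            ) < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            plane_from_points((0, 0, 0), (1, 1, 1), (2, 2, 2))

    @pytest.mark.parametrize(
        "coeffs, point, expected",
        [
            ((0, 0, 1, 0), (0, 0, 5), 5.0),
            ((1, 1, 1, 0), (1, 1, 1), np.sqrt(3)),
        ],
    )
    def test_point_plane_distance_closed_form(self, coeffs, point, expected):
        assert point_plane_distance(coeffs, point) == pytest.approx(expected)

    @given(scale=st.floats(min_value=-1e6, max_value=1e6).filter(lambda s: abs(s) > 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_distance_invariant_under_coefficient_scaling(self, scale):
        coeffs = (0.3, -1.2, 2.0, 4.5)
        p = (1.0, -2.0, 0.5)
        scaled = tuple(scale * c for c in coeffs)
        assert point_plane_distance(scaled, p) == pytest.approx(
            point_plane_distance(coeffs, p), rel=1e-9
        )

    def test_distance_matches_projection_oracle(self, rng):
        for _ in range(20):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            d = rng.normal(scale=10)
            plane = Plane(*n, d)
            p = rng.normal(scale=30, size=3)
            # project p onto the plane, measure the drop
            proj = p - float(plane.signed_distance(p)) * plane.normal
            assert point_plane_distance(plane, p) == pytest.approx(
                np.linalg.norm(p - proj), abs=1e-9
            )


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        R = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_compose_inverse_roundtrip(self, rng):
        a = RigidTransform.random(rng)
        b = RigidTransform.random(rng)
        pts = rng.normal(size=(10, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-9)

    def test_plane_transforms_consistently(self, rng):
        rt = RigidTransform.random(rng)
        plane = plane_from_points((0, 0, 0), (3, 0, 0), (0, 2, 0))
        moved = rt.apply_plane(plane)
        pts = np.array([[1.0, 1.0, 0.0], [5.0, -2.0, 0.0]])
        assert np.allclose(moved.signed_distance(rt.apply(pts)), 0.0, atol=1e-9)


class TestMembership:
    def test_unit_cube_examples(self):
        q = MeshQueries(unit_cube())
        assert point_in_solid(q, (0.5, 0.5, 0.5), eps=0.0)
        assert not point_in_solid(q, (2, 2, 2), eps=0.0)
        assert point_in_solid(q, (1.00005, 0.5, 0.5), eps=0.1)
        assert not point_in_solid(q, (1.2, 0.5, 0.5), eps=0.1)

    def test_agrees_with_analytic_sphere_oracle(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        q = MeshQueries(mesh)
        pts = rng.uniform(-12, 12, size=(10_000, 3))
        r = np.linalg.norm(pts, axis=1)
        clear = (r < 9.5) | (r > 10.5)  # away from the tessellation band
        inside = q.contains(pts)
        agree = np.mean(inside[clear] == (r[clear] < 10.0))
        assert agree >= 0.999

    def test_agrees_with_convex_hull_halfspace_oracle(self, rng):
        cloud = rng.normal(scale=10, size=(60, 3))
        hull = trimesh.convex.convex_hull(cloud)
        q = MeshQueries(hull)
        pts = rng.uniform(-25, 25, size=(4000, 3))
        # independent oracle: inside a convex hull iff behind every face plane
        origins = hull.triangles[:, 0]
        normals = hull.face_normals
        signed = np.einsum("pk,fk->pf", pts, normals) - np.einsum(
            "fk,fk->f", origins, normals
        )
        oracle = np.all(signed < -1e-6, axis=1)
        definite = np.abs(signed).min(axis=1) > 1e-3
        inside = q.contains(pts)
        assert np.mean(inside[definite] == oracle[definite]) >= 0.999

    def test_not_watertight_error_reports_open_edges(self):
        cube = unit_cube()
        broken = trimesh.Trimesh(
            vertices=cube.vertices.copy(), faces=cube.faces[:-1], process=False
        )
        with pytest.raises(NotWatertightError) as err:
            MeshQueries(broken)
        assert err.value.n_open_edges == 3

    def test_first_entry_distance_into_cube(self):
        q = MeshQueries(unit_cube())
        origins = np.array([[0.3, 0.4, 5.0], [0.3, 0.4, -3.0], [5.0, 5.0, 5.0]])
        t = q.first_entry(origins, np.array([0.0, 0.0, -1.0]))
        assert t[0] == pytest.approx(4.0, abs=1e-9)
        assert np.isinf(t[1])  # pointing away
        assert np.isinf(t[2])  # misses entirely

    def test_surface_distance_on_cube(self):
        q = MeshQueries(unit_cube())
        pts = np.array([[1.5, 0.5, 0.5], [0.5, 0.5, 0.5], [2.0, 2.0, 2.0]])
        d = q.surface_distance(pts)
        assert d[0] == pytest.approx(0.5, abs=1e-9)
        assert d[1] == pytest.approx(0.5, abs=1e-9)  # interior to nearest face
        assert d[2] == pytest.approx(np.sqrt(3.0), abs=1e-9)  # corner distance


class TestSurfaceArea:
    def test_cube_area(self):
        assert surface_area(unit_cube()) == pytest.approx(6.0)

    def test_sphere_area_converges_monotonically(self):
        areas = [
            surface_area(trimesh.creation.icosphere(subdivisions=k, radius=22.0))
            for k in range(4)
        ]
        target = 4 * np.pi * 22.0**2
        errors = [target - a for a in areas]
        assert all(e > 0 for e in errors)  # inscribed: always below
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] / target < 0.01

    def test_area_invariant_under_rigid_transform(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=7.0)
        rt = RigidTransform.random(rng)
        assert surface_area(rt.apply_mesh(mesh)) == pytest.approx(
            surface_area(mesh), rel=1e-6
        )
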