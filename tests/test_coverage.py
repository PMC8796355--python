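"""Coverage classification, quadrant partition, segmental ratios."""

import numpy as np
import pytest
import trimesh

from cupcov.coverage import (
    CoverageResult,
    QuadrantPlanes,
    classify_coverage,
    quadrant_labels,
    quadrant_planes,
    segmental_ucrs,
)
from cupcov.cup import CupPose, CupSpec, build_cup_mesh
from cupcov.frames import build_pelvic_frame
from cupcov.geometry import DegenerateGeometryError, Plane, RigidTransform
from cupcov.synthetic import half_space_fixture, spherical_zone_uncovered_fraction

from test_frames import canonical_landmarks


def eggshell_at(fx, subdivision=3):
    return build_cup_mesh(
        CupSpec.eggshell(subdivision), fx.pose, "outer_shell_only", fx.frame
    )


class TestClassifyCoverage:
    def test_fully_embedded_cup_has_zero_tucr(self):
        fx = half_space_fixture(-11.0)
        block = trimesh.creation.box(extents=[200, 200, 200])
        block.apply_translation(fx.pose.center)
        cov = classify_coverage(block, eggshell_at(fx))
        assert cov.tucr == 0.0

    def test_unreachable_bone_gives_tucr_one(self):
        fx = half_space_fixture(0.0)
        far = fx.bone.mesh.copy()
        far.apply_translation([500.0, 0, 0])
        cov = classify_coverage(far, eggshell_at(fx))
        assert cov.tucr == 1.0

    @pytest.mark.parametrize("gap", [-11.0, 0.0, 11.0])
    def test_tucr_matches_spherical_zone_closed_form(self, gap):
        fx = half_space_fixture(gap)
        cov = classify_coverage(fx.bone.mesh, eggshell_at(fx))
        assert cov.tucr == pytest.approx(
            spherical_zone_uncovered_fraction(gap, 22.0), abs=0.01
        )

    def test_axis_containing_face_gives_half(self):
        fx = half_space_fixture(0.0, face_contains_axis=True)
        cov = classify_coverage(fx.bone.mesh, eggshell_at(fx))
        assert cov.tucr == pytest.approx(0.5, abs=0.01)

    def test_refinement_stability(self):
        fx = half_space_fixture(11.0)
        t3 = classify_coverage(fx.bone.mesh, eggshell_at(fx, 3)).tucr
        t4 = classify_coverage(fx.bone.mesh, eggshell_at(fx, 4)).tucr
        assert abs(t4 - t3) < 0.01

    def test_axisymmetry_of_downstream_tucr(self):
        fx = half_space_fixture(11.0)
        mesh = eggshell_at(fx)
        u = fx.pose.polar_axis
        angle = np.deg2rad(17.0)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        rotated = mesh.copy()
        rotated.vertices = (mesh.vertices - fx.pose.center) @ R.T + fx.pose.center
        t0 = classify_coverage(fx.bone.mesh, mesh).tucr
        t1 = classify_coverage(fx.bone.mesh, rotated).tucr
        assert abs(t1 - t0) < 0.01

    def test_monotone_under_additional_bone(self):
        # stacking an extra face-adjacent block onto the slab (union of two
        # touching boxes) can only decrease every segmental ratio
        fx = half_space_fixture(11.0)
        planes = quadrant_planes(fx.bone.landmarks, fx.frame, fx.pose.center)
        cup = eggshell_at(fx)
        normal = -fx.pose.polar_axis
        extra = trimesh.creation.box(extents=[140.0, 140.0, 8.0])
        B = np.eye(4)
        from cupcov.cup import cup_basis

        B[:3, :3] = cup_basis(normal).T
        B[:3, 3] = fx.pose.center + 7.0 * normal  # spans offsets 3..11
        extra.apply_transform(B)
        union = trimesh.util.concatenate([fx.bone.mesh, extra])
        a = segmental_ucrs(classify_coverage(fx.bone.mesh, cup), planes)
        b = segmental_ucrs(classify_coverage(union, cup), planes)
        for k in ("asucr", "aiucr", "psucr", "piucr", "tucr"):
            assert getattr(b, k) <= getattr(a, k) + 1e-12


class TestQuadrantPlanes:
    def test_planes_contain_cup_center_and_are_perpendicular(self):
        lm = canonical_landmarks()
        frame = build_pelvic_frame(lm)
        center = np.array([45.0, -25.0, 10.0])
        qp = quadrant_planes(lm, frame, center)
        assert abs(float(qp.sagittal_q.signed_distance(center))) < 1e-9
        assert abs(float(qp.horizontal_q.signed_distance(center))) < 1e-9
        assert abs(qp.sagittal_q.normal @ qp.horizontal_q.normal) < 1e-9

    def test_horizontal_normal_points_inferior(self):
        lm = canonical_landmarks()
        frame = build_pelvic_frame(lm)
        qp = quadrant_planes(lm, frame, np.array([45.0, -25.0, 10.0]))
        # cup center sits inferior to the ipsilateral ASIS
        assert qp.horizontal_q.normal @ frame.superior_axis < 0

    def test_center_on_asis_line_rejected(self):
        lm = canonical_landmarks()
        frame = build_pelvic_frame(lm)
        with pytest.raises(DegenerateGeometryError):
            quadrant_planes(lm, frame, np.array([0.0, 0.0, 80.0]))

    def test_equivariance_under_rigid_transform(self, rng):
        lm = canonical_landmarks()
        frame = build_pelvic_frame(lm)
        center = np.array([45.0, -25.0, 10.0])
        qp = quadrant_planes(lm, frame, center)
        rt = RigidTransform.random(rng)
        lm2 = lm.transformed(rt)
        qp2 = quadrant_planes(lm2, build_pelvic_frame(lm2), rt.apply(center))
        pts = rng.normal(scale=30, size=(20, 3)) + center
        assert np.allclose(
            qp2.sagittal_q.signed_distance(rt.apply(pts)),
            qp.sagittal_q.signed_distance(pts),
            atol=1e-6,
        )


class TestSegmentalUCRs:
    def _symmetric_setup(self):
        """Two orthogonal planes through the cup center whose intersection
        line is the polar axis: they cut the hemisphere into four equal
        segments."""
        center = np.zeros(3)
        u = np.array([0.0, 0.0, 1.0])
        pose = CupPose(center, u)
        mesh = build_cup_mesh(CupSpec.eggshell(3), pose, "outer_shell_only")
        p1 = Plane.from_point_normal(center, [1.0, 0.0, 0.0])
        p2 = Plane.from_point_normal(center, [0.0, 1.0, 0.0])
        planes = QuadrantPlanes(sagittal_q=p1, horizontal_q=p2, cup_center=center)
        return mesh, planes

    def test_fully_uncovered_symmetric_split_is_quarters(self):
        mesh, planes = self._symmetric_setup()
        cov = CoverageResult(
            covered=np.zeros(len(mesh.faces), dtype=bool),
            facet_areas=mesh.area_faces,
            facet_centroids=mesh.triangles.mean(axis=1),
            eps_mm=0.1,
        )
        ucrs = segmental_ucrs(cov, planes)
        for v in (ucrs.asucr, ucrs.aiucr, ucrs.psucr, ucrs.piucr):
            assert v == pytest.approx(0.25, abs=0.01)
        assert ucrs.tucr == pytest.approx(1.0, abs=1e-12)

    def test_zero_uncovered_gives_all_zero(self):
        mesh, planes = self._symmetric_setup()
        cov = CoverageResult(
            covered=np.ones(len(mesh.faces), dtype=bool),
            facet_areas=mesh.area_faces,
            facet_centroids=mesh.triangles.mean(axis=1),
            eps_mm=0.1,
        )
        ucrs = segmental_ucrs(cov, planes)
        assert ucrs.tucr == 0.0
        assert ucrs.asucr == ucrs.aiucr == ucrs.psucr == ucrs.piucr == 0.0

    def test_partition_is_exact(self):
        mesh, planes = self._symmetric_setup()
        labels = quadrant_labels(mesh.triangles.mean(axis=1), planes)
        assert len(labels) == len(mesh.faces)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}

    def test_synthetic_recovery_within_tolerance(self, default_hip, default_hip_result):
        gt = default_hip.ground_truth
        got = default_hip_result["ucrs"]
        for k in ("asucr", "aiucr", "psucr", "piucr"):
            assert getattr(got, k) == pytest.approx(getattr(gt, k), abs=0.01)

    def test_segmental_sum_equals_tucr(self, default_hip_result):
        u = default_hip_result["ucrs"]
        assert u.asucr + u.aiucr + u.psucr + u.piucr == pytest.approx(
            u.tucr, abs=1e-12
        )
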