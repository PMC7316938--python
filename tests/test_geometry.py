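"""Pose representation and the four planned-vs-placed deviation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implacc import (
    DeviationRecord,
    RigidTransform,
    angular_deviation,
    apply_transform,
    axis_of,
    depth_deviation,
    deviate,
    global_deviation,
    lateral_deviation,
)
from implacc.geometry import GeometryError, PairingError, UndefinedLateralError

from .conftest import make_pose, oracle_deviations, random_pose_pair, random_rigid

SIN10, COS10 = np.sin(np.radians(10)), np.cos(np.radians(10))


class TestPoseValidation:
    def test_degenerate_pose_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            make_pose([1, 2, 3], [1, 2, 3])

    def test_declared_length_must_match_axis(self):
        with pytest.raises(GeometryError, match="inconsistent"):
            make_pose([0, 0, 0], [0, 0, 13], length_mm=15.0)
        make_pose([0, 0, 0], [0, 0, 13], length_mm=13.0)  # consistent: fine

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(GeometryError, match="non-finite"):
            make_pose([0, 0, np.nan], [0, 0, 13])


class TestAxis:
    @pytest.mark.parametrize(
        "shoulder, apex, expected",
        [
            ([0, 0, 0], [0, 0, 13], [0, 0, 1]),
            ([1, 1, 1], [1, 1, 14], [0, 0, 1]),  # translation invariance
            ([0, 0, 0], [3, 0, 4], [0.6, 0, 0.8]),  # 3-4-5 triple
        ],
    )
    def test_axis_examples(self, shoulder, apex, expected):
        np.testing.assert_allclose(axis_of(make_pose(shoulder, apex)), expected, atol=1e-12)

    def test_axis_is_unit(self, rng):
        for _ in range(50):
            p, q = random_pose_pair(rng)
            assert abs(np.linalg.norm(axis_of(p)) - 1.0) < 1e-12


class TestAngular:
    def test_identical_axes_zero(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([1, 2, 3], [1, 2, 16], role="placed")
        assert angular_deviation(p, q) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_axes(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0, 0, 0], [13, 0, 0], role="placed")
        assert angular_deviation(p, q) == pytest.approx(90.0, abs=1e-12)

    def test_analytic_five_degrees(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0, 0, 0], 13 * np.array([np.sin(np.radians(5)), 0, np.cos(np.radians(5))]),
                      role="placed")
        assert angular_deviation(p, q) == pytest.approx(5.0, abs=1e-10)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            p, q = random_pose_pair(rng)
            assert angular_deviation(p, q) == pytest.approx(angular_deviation(q, p), abs=1e-12)

    def test_flipped_implant_warns_not_folds(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0, 0, 13], [0, 0, 0.1], role="placed")
        with pytest.warns(UserWarning, match="flipped"):
            ang = angular_deviation(p, q)
        assert ang > 170.0


class TestGlobalLateralDepth:
    def test_coincident_shoulders(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0, 0, 0], [1, 0, 13], role="placed")
        assert global_deviation(p, q) == 0.0

    def test_global_345(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0.8, 0, 0.6], [0.8, 0, 13.6], role="placed")
        assert global_deviation(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_global_single_axis(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([2.6, 0, 0], [2.6, 0, 13], role="placed")
        assert global_deviation(p, q) == pytest.approx(2.6, abs=1e-12)

    def test_lateral_parallel_axes(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0.8, 0, 0.6], [0.8, 0, 13.6], role="placed")
        lat, C = lateral_deviation(p, q)
        assert lat == pytest.approx(0.8, abs=1e-12)
        np.testing.assert_allclose(C, [0.8, 0, 0], atol=1e-12)

    def test_lateral_identity(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0, 0, 0], [0, 0, 13], role="placed")
        lat, C = lateral_deviation(p, q)
        assert lat == 0.0

    def test_lateral_tilted_axis_matches_parametric_construction(self):
        # placed axis tilted 10 degrees: C = B - (B_z / cos10) * v
        p = make_pose([0, 0, 0], [0, 0, 13])
        v = np.array([SIN10, 0, COS10])
        B = np.array([0.5, 0, 1.0])
        q = make_pose(B, B + 13 * v, role="placed")
        lat, C = lateral_deviation(p, q)
        C_expected = B - (1.0 / COS10) * v
        np.testing.assert_allclose(C, C_expected, atol=1e-12)
        assert lat == pytest.approx(np.linalg.norm(C_expected), abs=1e-12)

    def test_lateral_undefined_when_axis_in_plane(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([1, 0, 0], [14, 0, 0], role="placed")  # horizontal
        with pytest.raises(UndefinedLateralError):
            lateral_deviation(p, q)

    def test_depth_axial_projection(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0.8, 0, 0.6], [0.8, 0, 13.6], role="placed")
        depth, signed, D = depth_deviation(p, q)
        assert depth == pytest.approx(0.6, abs=1e-12)
        assert signed == pytest.approx(+0.6, abs=1e-12)  # apical
        np.testing.assert_allclose(D, [0, 0, 0.6], atol=1e-12)

    def test_depth_zero_for_pure_perpendicular_offset(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([1.3, -0.4, 0], [1.3, -0.4, 13], role="placed")
        depth, signed, _ = depth_deviation(p, q)
        assert depth == pytest.approx(0.0, abs=1e-12)


class TestDeviate:
    def test_identical_poses_zero_record(self):
        p = make_pose([1, 2, 3], [1, 2, 16])
        q = make_pose([1, 2, 3], [1, 2, 16], role="placed")
        r = deviate(p, q)
        assert r.angular_deg == r.global_mm == r.lateral_mm == r.depth_mm == 0.0

    def test_parallel_axis_composition(self):
        # perpendicular offset 0.8, axial offset 0.6 -> 1.0 / 0.8 / 0.6 / 0
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([0.8, 0, 0.6], [0.8, 0, 13.6], role="placed")
        r = deviate(p, q)
        assert r.global_mm == pytest.approx(1.0, abs=1e-12)
        assert r.lateral_mm == pytest.approx(0.8, abs=1e-12)
        assert r.depth_mm == pytest.approx(0.6, abs=1e-12)
        assert r.angular_deg == pytest.approx(0.0, abs=1e-12)

    def test_matches_component_operations_exactly(self, rng):
        p, q = random_pose_pair(rng)
        r = deviate(p, q)
        assert r.angular_deg == angular_deviation(p, q)
        assert r.global_mm == global_deviation(p, q)
        assert (r.lateral_mm, *[]) == (lateral_deviation(p, q)[0],)
        assert r.depth_mm == depth_deviation(p, q)[0]

    def test_agrees_with_point_construction_oracle(self, rng):
        for _ in range(100):
            p, q = random_pose_pair(rng)
            r = deviate(p, q)
            o = oracle_deviations(p, q)
            assert r.angular_deg == pytest.approx(o["angular_deg"], abs=1e-9)
            assert r.global_mm == pytest.approx(o["global_mm"], abs=1e-9)
            assert r.lateral_mm == pytest.approx(o["lateral_mm"], abs=1e-9)
            assert r.depth_mm == pytest.approx(o["depth_mm"], abs=1e-9)
            np.testing.assert_allclose(r.point_c, o["point_c"], atol=1e-9)
            np.testing.assert_allclose(r.point_d, o["point_d"], atol=1e-9)

    def test_mismatched_pair_rejected(self):
        p = make_pose([0, 0, 0], [0, 0, 13], patient="p1")
        q = make_pose([0, 0, 0], [0, 0, 13], role="placed", patient="p2")
        with pytest.raises(PairingError):
            deviate(p, q)

    def test_undefined_lateral_marked_missing_only(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        q = make_pose([1, 0, 0.5], [14, 0, 0.5], role="placed")
        r = deviate(p, q)
        assert r.lateral_mm is None and r.point_c is None
        assert r.global_mm is not None and r.depth_mm is not None

    def test_depth_never_exceeds_global(self, rng):
        for _ in range(200):
            p, q = random_pose_pair(rng)
            r = deviate(p, q)
            assert r.depth_mm <= r.global_mm + 1e-12


class TestInvariants:
    def test_rigid_motion_invariance(self, rng):
        for _ in range(50):
            p, q = random_pose_pair(rng)
            t = random_rigid(rng)
            r0 = deviate(p, q)
            r1 = deviate(apply_transform(p, t), apply_transform(q, t))
            assert r1.angular_deg == pytest.approx(r0.angular_deg, abs=1e-9)
            assert r1.global_mm == pytest.approx(r0.global_mm, abs=1e-9)
            assert r1.lateral_mm == pytest.approx(r0.lateral_mm, abs=1e-9)
            assert r1.depth_mm == pytest.approx(r0.depth_mm, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        off=st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
        ax=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
    )
    def test_pythagorean_split_for_parallel_axes(self, off, ax):
        a = np.asarray(ax)
        if np.linalg.norm(a) < 1e-3:
            a = np.array([0.0, 0.0, 1.0])
        a = a / np.linalg.norm(a)
        A = np.array([2.0, -1.0, 4.0])
        B = A + np.asarray(off)
        p = make_pose(A, A + 13 * a)
        q = make_pose(B, B + 13 * a, role="placed")
        r = deviate(p, q)
        assert r.angular_deg == pytest.approx(0.0, abs=1e-9)
        assert r.global_mm**2 == pytest.approx(r.lateral_mm**2 + r.depth_mm**2, rel=1e-9, abs=1e-15)

    def test_deviate_of_pose_with_itself_is_zero(self, rng):
        for _ in range(30):
            p, _ = random_pose_pair(rng)
            q = make_pose(p.shoulder, p.apex, role="placed")
            r = deviate(p, q)
            assert max(r.angular_deg, r.global_mm, r.lateral_mm, r.depth_mm) == 0.0


class TestRigidTransform:
    def test_identity_leaves_pose_unchanged(self):
        p = make_pose([1, 2, 3], [1, 2, 16])
        q = apply_transform(p, RigidTransform.identity())
        np.testing.assert_array_equal(q.shoulder, p.shoulder)
        np.testing.assert_array_equal(q.apex, p.apex)

    def test_pure_translation_moves_only_globally(self):
        p = make_pose([0, 0, 0], [0, 0, 13])
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        q = apply_transform(p, t)
        r = deviate(p, make_pose(q.shoulder, q.apex, role="placed"))
        assert r.global_mm == pytest.approx(np.sqrt(14.0), abs=1e-12)
        assert r.angular_deg == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_about_z(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        p = make_pose([0, 0, 0], [13, 0, 0])
        q = apply_transform(p, RigidTransform(Rz, np.zeros(3)))
        np.testing.assert_allclose(axis_of(q), [0, 1, 0], atol=1e-12)

    def test_improper_rotation_rejected(self):
        with pytest.raises(GeometryError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_axis_length_preserved(self, rng):
        p, _ = random_pose_pair(rng)
        t = random_rigid(rng)
        assert apply_transform(p, t).axis_length_mm == pytest.approx(p.axis_length_mm, abs=1e-9)

    def test_compose_and_inverse(self, rng):
        t1, t2 = random_rigid(rng), random_rigid(rng)
        pts = rng.uniform(-5, 5, (10, 3))
        np.testing.assert_allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-9)
        np.testing.assert_allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-9)


class TestDeviationRecordInvariants:
    def test_signed_magnitude_consistency_enforced(self):
        with pytest.raises(GeometryError):
            DeviationRecord(
                patient_id="p", location="13", angular_deg=1.0, global_mm=1.0,
                lateral_mm=0.5, depth_mm=0.5, depth_signed_mm=0.7,
            )

    def test_negative_metric_rejected(self):
        with pytest.raises(GeometryError):
            DeviationRecord(
                patient_id="p", location="13", angular_deg=-1.0, global_mm=1.0,
                lateral_mm=0.5, depth_mm=0.5, depth_signed_mm=-0.5,
            )
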