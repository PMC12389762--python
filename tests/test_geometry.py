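"""Rigid-transform algebra, Euler round-trips and the similar-triangles
pixel-to-phantom mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nwirecal.exceptions import AlphaRangeError, DegenerateGeometryError
from nwirecal.geometry import (
    CalibrationState,
    NWireLayer,
    PhantomGeometry,
    PoseParams6,
    RigidTransform,
    alpha_from_triplet,
    compose,
    default_phantom,
    image_point_to_metric,
    matrix_to_pose,
    middle_point_phantom,
    pose_to_matrix,
)

angles_st = st.floats(-np.pi, np.pi, allow_nan=False)
trans_st = st.floats(-100, 100, allow_nan=False)


class TestRigidTransform:
    def test_identity_and_inverse_compose_to_identity(self, rng):
        for _ in range(20):
            p = PoseParams6(rng.uniform(-np.pi, np.pi, 3), rng.uniform(-50, 50, 3))
            t = pose_to_matrix(p)
            ti = compose(t, t.inverse())
            assert np.abs(ti.rotation - np.eye(3)).max() < 1e-9
            assert np.abs(ti.translation).max() < 1e-9

    def test_compose_identity_is_neutral(self):
        t = pose_to_matrix(PoseParams6(np.array([0.3, -0.2, 0.1]), np.array([1.0, 2.0, 3.0])))
        out = compose(RigidTransform.identity(), t)
        assert np.allclose(out.as_matrix(), t.as_matrix())

    def test_pure_translations_add(self):
        t1 = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        t2 = RigidTransform(np.eye(3), np.array([0.0, 2.0, 0.0]))
        assert np.allclose(compose(t1, t2).translation, [1.0, 2.0, 0.0])

    def test_rejects_reflection(self):
        r = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(r, np.zeros(3))

    def test_chain_round_trip_preserves_points(self, rng):
        """P -> U through the inverse chain and back reproduces the point."""
        ts = [
            pose_to_matrix(PoseParams6(rng.uniform(-1, 1, 3), rng.uniform(-30, 30, 3)))
            for _ in range(3)
        ]
        chain = ts[0] @ ts[1] @ ts[2]
        pts = rng.uniform(-40, 40, (50, 3))
        back = chain.apply(chain.inverse().apply(pts))
        assert np.abs(back - pts).max() < 1e-9


class TestPoseConversion:
    def test_zero_pose_is_identity(self):
        t = pose_to_matrix(PoseParams6.zero())
        assert np.allclose(t.as_matrix(), np.eye(4))

    def test_translation_only(self):
        t = pose_to_matrix(PoseParams6(np.zeros(3), np.array([1.0, 2.0, 3.0])))
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, [1.0, 2.0, 3.0])

    def test_quarter_turn_about_z(self):
        t = pose_to_matrix(PoseParams6(np.array([np.pi / 2, 0, 0]), np.zeros(3)))
        assert np.abs(t.apply([1.0, 0.0, 0.0]) - np.array([0.0, 1.0, 0.0])).max() < 1e-12

    def test_identity_maps_to_zero_pose(self):
        p = matrix_to_pose(RigidTransform.identity())
        assert np.allclose(p.angles, 0) and np.allclose(p.translation, 0)

    def test_round_trip_over_random_transforms(self, rng):
        for _ in range(1000):
            p = PoseParams6(rng.uniform(-np.pi, np.pi, 3), rng.uniform(-100, 100, 3))
            t = pose_to_matrix(p)
            t2 = pose_to_matrix(matrix_to_pose(t))
            assert np.abs(t2.as_matrix() - t.as_matrix()).max() < 1e-9

    @pytest.mark.parametrize("pitch", [np.pi / 2, -np.pi / 2])
    def test_gimbal_lock_reconstructs(self, pitch):
        p = PoseParams6(np.array([0.7, pitch, 0.3]), np.array([1.0, -2.0, 3.0]))
        t = pose_to_matrix(p)
        t2 = pose_to_matrix(matrix_to_pose(t))
        assert np.abs(t2.as_matrix() - t.as_matrix()).max() < 1e-9

    def test_non_rigid_matrix_rejected(self):
        bad = np.eye(3) * 1.01
        with pytest.raises(ValueError):
            matrix_to_pose(RigidTransform(bad, np.zeros(3)))


class TestCalibrationState:
    def test_fourteen_free_scalars_round_trip(self, rng):
        v = np.concatenate([rng.uniform(-1, 1, 12), [0.1, 0.2]])
        s = CalibrationState.from_vector(v)
        assert np.allclose(s.as_vector(), v)
        assert s.as_vector().shape == (14,)

    def test_positive_scales_enforced(self):
        with pytest.raises(ValueError):
            CalibrationState(PoseParams6.zero(), PoseParams6.zero(), -0.1, 0.1)


class TestImagePointToMetric:
    def test_origin(self):
        assert np.allclose(image_point_to_metric(0, 0, 0.3, 0.7), [0, 0, 0])

    def test_scaling(self):
        assert np.allclose(image_point_to_metric(10, 20, 0.1, 0.2), [1.0, 4.0, 0.0])

    def test_unit_scales_pass_through(self):
        assert np.allclose(image_point_to_metric(37, 19, 1.0, 1.0), [37.0, 19.0, 0.0])

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            image_point_to_metric(1, 1, 0.0, 0.1)


class TestAlpha:
    def test_b_at_a_gives_zero(self):
        assert alpha_from_triplet((5, 5), (5, 5), (10, 5)) == 0.0

    def test_midpoint_gives_half(self):
        assert alpha_from_triplet((0, 0), (5, 0), (10, 0)) == pytest.approx(0.5)

    def test_hand_computed_ratio(self):
        # |B-A| = 30, |C-A| = 75 -> 0.4
        assert alpha_from_triplet((100, 200), (130, 200), (175, 200)) == pytest.approx(0.4)

    def test_degenerate_triplet_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            alpha_from_triplet((1, 1), (2, 2), (1, 1))

    def test_out_of_band_alpha_rejected(self):
        with pytest.raises(AlphaRangeError):
            alpha_from_triplet((0, 0), (20, 0), (10, 0))  # alpha = 2

    @given(
        theta=st.floats(-np.pi, np.pi),
        scale=st.floats(0.1, 10.0),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_similarity_transforms(self, theta, scale, tx, ty):
        """alpha is unchanged by in-plane rotation, translation, scaling."""
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [10.0, 0.0]])
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = scale * pts @ rot.T + np.array([tx, ty])
        a0 = alpha_from_triplet(*pts)
        a1 = alpha_from_triplet(*moved)
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestMiddlePoint:
    def _layer(self):
        a = np.array([0.0, 0.0, 10.0])
        b = a + np.array([25.0, 0.0, 0.0])
        c = a + np.array([0.0, 50.0, 0.0])
        return NWireLayer(0, 10.0, a, b, c, a + (b - a) + (c - a))

    def test_alpha_zero_returns_a(self):
        lay = self._layer()
        assert np.allclose(middle_point_phantom(0.0, lay), lay.a)

    def test_alpha_one_returns_d(self):
        lay = self._layer()
        assert np.allclose(middle_point_phantom(1.0, lay), lay.d)

    def test_direct_formula(self):
        # alpha=0.4, |a-b|=25, |a-c|=50, z=10 -> (10, 20, 10)
        assert np.allclose(middle_point_phantom(0.4, self._layer()), [10.0, 20.0, 10.0])

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            middle_point_phantom(1.2, self._layer())

    def test_exact_for_perpendicular_cut(self):
        """For a cut plane perpendicular to the wires, alpha recovered
        from the analytic intersections reproduces B exactly."""
        phantom = default_phantom()
        for lay in phantom.layers:
            for frac in (0.1, 0.5, 0.83):
                # plane y = frac * wire_length intersects the wires at
                a_img = lay.a + frac * (lay.c - lay.a)
                b_img = lay.a + frac * (lay.d - lay.a)
                c_img = lay.b + frac * (lay.d - lay.b)
                alpha = alpha_from_triplet(a_img[:2], b_img[:2], c_img[:2])
                assert np.abs(middle_point_phantom(alpha, lay) - b_img).max() < 1e-9


class TestPhantomGeometry:
    def test_default_phantom_spacings(self):
        ph = default_phantom()
        assert ph.n_layers == 3
        zs = [lay.z for lay in ph.layers]
        assert zs == [0.0, -10.0, -20.0]
        assert all(lay.wire_spacing == 25.0 for lay in ph.layers)

    def test_non_monotone_layers_rejected(self):
        lay = default_phantom().layers[0]
        with pytest.raises(ValueError, match="monotone"):
            PhantomGeometry((lay, lay))

    def test_d_identity_enforced(self):
        a = np.zeros(3)
        with pytest.raises(ValueError, match="d must equal"):
            NWireLayer(0, 0.0, a, a + [25, 0, 0], a + [0, 25, 0], a + [20, 20, 1])
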