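"""Relative-motion derivation and the ICOR/IAOR formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointaxis.core_kinematics import (
    BodyTrajectory,
    GridMismatchError,
    SingularSampleError,
    axis_direction,
    icor_fixed_frame,
    icor_relative,
    relative_motion,
    trajectory_from_poses,
)


def _rotz(a):
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(np.shape(a) + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def _static_identity(t):
    n = t.size
    return BodyTrajectory(
        t=t,
        R=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        p=np.zeros((n, 3)),
        v=np.zeros((n, 3)),
        w=np.zeros((n, 3)),
    )


def _smooth_random_trajectory(t, rng):
    """Rigid trajectory with sinusoidal pose and exact analytic velocities."""
    amp_p = rng.uniform(-0.5, 0.5, 3)
    f_p = rng.uniform(0.1, 0.4, 3)
    a0, fa = rng.uniform(-1, 1), rng.uniform(0.1, 0.3)
    ang = a0 * np.sin(2 * np.pi * fa * t)
    dang = a0 * 2 * np.pi * fa * np.cos(2 * np.pi * fa * t)
    p = amp_p * np.sin(2 * np.pi * f_p * t[:, None])
    v = amp_p * 2 * np.pi * f_p * np.cos(2 * np.pi * f_p * t[:, None])
    w = np.zeros((t.size, 3))
    w[:, 2] = dang
    return BodyTrajectory(t=t, R=_rotz(ang), p=p, v=v, w=w)


class TestRelativeMotion:
    def test_child_equals_parent_gives_zero(self):
        t = np.arange(50) / 100.0
        rng = np.random.default_rng(0)
        tr = _smooth_random_trajectory(t, rng)
        rm = relative_motion(tr, tr)
        assert np.allclose(rm.r_rel, 0.0, atol=1e-12)
        assert np.allclose(rm.v_rel, 0.0, atol=1e-12)
        assert np.allclose(rm.w_rel, 0.0, atol=1e-12)

    def test_static_parent_reduces_to_world_quantities(self):
        t = np.arange(200) / 100.0
        parent = _static_identity(t)
        p_c = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        v_c = np.stack([-np.sin(t), np.cos(t), np.zeros_like(t)], axis=1)
        w_c = np.tile([0.0, 0.0, 1.0], (t.size, 1))
        child = BodyTrajectory(t=t, R=_rotz(t), p=p_c, v=v_c, w=w_c)
        rm = relative_motion(parent, child)
        assert np.allclose(rm.r_rel, p_c, atol=1e-12)
        assert np.allclose(rm.v_rel, v_c, atol=1e-12)
        assert np.allclose(rm.w_rel, w_c, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_v_rel_is_parent_frame_derivative_of_r_rel(self, seed):
        """Central differences of r_rel must reproduce v_rel (the defining
        consistency property of the relative-motion formulas)."""
        t = np.arange(400) / 100.0
        rng = np.random.default_rng(seed)
        parent = _smooth_random_trajectory(t, rng)
        child = _smooth_random_trajectory(t, rng)
        rm = relative_motion(parent, child)
        dt = t[1] - t[0]
        fd = (rm.r_rel[2:] - rm.r_rel[:-2]) / (2 * dt)
        err = np.linalg.norm(fd - rm.v_rel[1:-1], axis=1)
        assert err.max() < 5e-3  # O(dt^2) for smooth sinusoidal motion

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(10) / 100.0
        t2 = np.arange(10) / 100.0 + 0.5
        a = _static_identity(t1)
        b = _static_identity(t2)
        with pytest.raises(GridMismatchError):
            relative_motion(a, b)


class TestIcorFixedFrame:
    @pytest.mark.parametrize(
        "w, v, r, expected",
        [
            ((0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 0, 0)),
            ((0, 0, 2), (0, 0, 0), (0.3, -0.2, 0), (0.3, -0.2, 0)),
        ],
    )
    def test_hand_cases(self, w, v, r, expected):
        assert np.allclose(icor_fixed_frame(w, v, r), expected, atol=1e-12)

    def test_singular_raises(self):
        with pytest.raises(SingularSampleError):
            icor_fixed_frame((0, 0, 1e-12), (1, 0, 0), (0, 0, 0))

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_velocity_field_minimizer(self, seed):
        """The formula must land on the point where the planar rigid-body
        velocity field has minimal magnitude (found by dense grid search)."""
        rng = np.random.default_rng(seed)
        wz = rng.uniform(0.5, 3.0)
        w = np.array([0.0, 0.0, wz])
        r = np.append(rng.uniform(-1, 1, 2), 0.0)
        v = np.append(rng.uniform(-1, 1, 2), 0.0)
        c = icor_fixed_frame(w, v, r)
        xs = np.linspace(-3, 3, 601)
        X, Y = np.meshgrid(xs, xs)
        pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)
        speeds = np.linalg.norm(v + np.cross(w, pts - r), axis=1)
        best = pts[np.argmin(speeds)]
        assert np.linalg.norm(c - best) < 2 * (xs[1] - xs[0])


class TestAxisDirection:
    @pytest.mark.parametrize(
        "w, expected",
        [((0, 0, 5), (0, 0, 1)), ((3, 4, 0), (0.6, 0.8, 0))],
    )
    def test_normalization(self, w, expected):
        assert np.allclose(axis_direction(w), expected, atol=1e-12)

    @given(
        st.tuples(
            *[st.floats(-10, 10, allow_nan=False) for _ in range(3)]
        ).filter(lambda w: np.linalg.norm(w) > 1e-6)
    )
    @settings(max_examples=50, deadline=None)
    def test_unit_and_parallel(self, w):
        e = axis_direction(np.array(w))
        assert abs(np.linalg.norm(e) - 1.0) < 1e-12
        assert np.linalg.norm(np.cross(e, w)) < 1e-9 * np.linalg.norm(w)


class TestIcorRelative:
    def test_pure_translation_all_invalid(self):
        t = np.arange(100) / 100.0
        parent = _static_identity(t)
        child = _static_identity(t)
        child.p = child.p + np.outer(t, [1.0, 0.0, 0.0])
        child.v = child.v + np.array([1.0, 0.0, 0.0])
        axes = icor_relative(relative_motion(parent, child))
        assert axes.n_valid == 0
        assert np.all(np.isnan(axes.c[~axes.valid]))

    def test_pendulum_icor_at_joint(self, pendulum):
        """Noisefree pendulum: every ICOR sits on the inter-link joint."""
        parent, child, truth = pendulum
        axes = icor_relative(relative_motion(parent, child))
        assert axes.n_valid > 900
        dev = axes.c[axes.valid] - truth.center_parent
        assert np.abs(dev).max() < 1e-9

    def test_ball_joint_lines_hit_center(self, ball):
        parent, child, truth = ball
        axes = icor_relative(relative_motion(parent, child))
        d = truth.center_parent - axes.c[axes.valid]
        e = axes.e[axes.valid]
        perp = d - np.einsum("ni,ni->n", d, e)[:, None] * e
        assert np.linalg.norm(perp, axis=1).max() < 1e-9

    def test_perpendicular_offset_invariant(self, knee):
        parent, child, _ = knee
        rm = relative_motion(parent, child)
        axes = icor_relative(rm)
        v = axes.valid
        dots = np.einsum(
            "ni,ni->n", axes.c[v] - rm.r_rel[v], rm.w_rel[v]
        )
        scale = np.linalg.norm(axes.c[v] - rm.r_rel[v], axis=1) * np.linalg.norm(
            rm.w_rel[v], axis=1
        )
        assert np.abs(dots).max() < 1e-9 * max(scale.max(), 1.0)

    def test_velocity_field_vanishes_at_icor(self, knee):
        """At every valid step the relative velocity field, evaluated at the
        ICOR, has no component perpendicular to the axis."""
        parent, child, _ = knee
        rm = relative_motion(parent, child)
        axes = icor_relative(rm)
        v = axes.valid
        vel_at_c = rm.v_rel[v] + np.cross(rm.w_rel[v], axes.c[v] - rm.r_rel[v])
        e = axes.e[v]
        perp = vel_at_c - np.einsum("ni,ni->n", vel_at_c, e)[:, None] * e
        assert np.linalg.norm(perp, axis=1).max() < 1e-9

    def test_planar_icor_independent_of_tracked_point(self, knee):
        """For planar relative motion the ICOR must not depend on which
        child-frame point the sensor tracks."""
        parent, child, _ = knee
        d = np.array([0.07, -0.12, 0.0])
        shifted = BodyTrajectory(
            t=child.t,
            R=child.R,
            p=child.p + np.einsum("nij,j->ni", child.R, d),
            v=child.v + np.cross(child.w, np.einsum("nij,j->ni", child.R, d)),
            w=child.w,
        )
        a1 = icor_relative(relative_motion(parent, child))
        a2 = icor_relative(relative_motion(parent, shifted))
        both = a1.valid & a2.valid
        assert np.abs(a1.c[both] - a2.c[both]).max() < 1e-9

    def test_3d_line_independent_of_tracked_point(self, ball):
        """In 3D the point on the axis moves with the tracked point but the
        line itself does not."""
        parent, child, _ = ball
        d = np.array([0.04, 0.03, -0.06])
        shifted = BodyTrajectory(
            t=child.t,
            R=child.R,
            p=child.p + np.einsum("nij,j->ni", child.R, d),
            v=child.v + np.cross(child.w, np.einsum("nij,j->ni", child.R, d)),
            w=child.w,
        )
        a1 = icor_relative(relative_motion(parent, child))
        a2 = icor_relative(relative_motion(parent, shifted))
        both = a1.valid & a2.valid
        delta = a2.c[both] - a1.c[both]
        e = a1.e[both]
        perp = delta - np.einsum("ni,ni->n", delta, e)[:, None] * e
        assert np.linalg.norm(perp, axis=1).max() < 1e-9
        assert np.abs(np.abs(np.einsum("ni,ni->n", a1.e[both], a2.e[both])) - 1).max() < 1e-12


def test_trajectory_from_poses_recovers_velocities():
    t = np.arange(500) / 100.0
    rng = np.random.default_rng(3)
    exact = _smooth_random_trajectory(t, rng)
    fd = trajectory_from_poses(t, exact.R, exact.p)
    assert np.abs(fd.v[2:-2] - exact.v[2:-2]).max() < 5e-3
    assert np.abs(fd.w[2:-2] - exact.w[2:-2]).max() < 5e-3
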