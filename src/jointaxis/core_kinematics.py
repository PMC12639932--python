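"""Analytical instantaneous center/axis of rotation from rigid-segment motion.

The motion of a rigid body can, at every instant, be read as a pure rotation
about a momentary point (planar: the ICOR) or line (3D: the IAOR).  For two
moving segments connected by a joint, the ICOR/IAOR of the *relative* motion
traces the joint center or axis — fixed for revolute and ball joints, moving
with joint angle for joints like the tibiofemoral joint.

Everything here is pure computation on in-memory time series: the relative
motion of a child sensor frame with respect to a parent sensor frame, and the
per-step ICOR point / IAOR line derived from it.  All estimator-facing
quantities are expressed in the parent sensor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS_OMEGA",
    "SingularSampleError",
    "GridMismatchError",
    "BodyTrajectory",
    "RelativeMotion",
    "AxisSampleSeries",
    "relative_motion",
    "icor_fixed_frame",
    "icor_relative",
    "axis_direction",
    "trajectory_from_poses",
]

#: Default angular-velocity magnitude below which an ICOR sample is singular,
#: rad/s.  Set to 0 to disable the guard (singular steps then only occur at
#: exactly zero angular velocity; near-zero steps produce the large outliers
#: that downstream outlier removal is designed to absorb).
EPS_OMEGA = 1e-8


class SingularSampleError(ValueError):
    """Angular velocity too small for a well-defined rotation center."""


class GridMismatchError(ValueError):
    """Two trajectories do not share the same time grid."""


def _as_points(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must have shape (N, 3), got {a.shape}")
    return a


@dataclass
class BodyTrajectory:
    """Uniformly sampled pose and velocity of one segment's sensor frame.

    Attributes
    ----------
    t : (N,) array
        Time, seconds, strictly increasing uniform grid.
    R : (N, 3, 3) array
        World-from-body rotation per step (columns are the body axes in
        world coordinates).
    p : (N, 3) array
        World position of the frame origin, meters.
    v : (N, 3) array
        World linear velocity of the origin, m/s.
    w : (N, 3) array
        Angular velocity in world coordinates, rad/s.
    """

    t: np.ndarray
    R: np.ndarray
    p: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.p = _as_points(self.p, "p")
        self.v = _as_points(self.v, "v")
        self.w = _as_points(self.w, "w")
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.t.ndim != 1 or any(
            arr.shape[0] != n for arr in (self.R, self.p, self.v, self.w)
        ):
            raise ValueError("t, R, p, v, w must share length N")
        if self.R.shape[1:] != (3, 3):
            raise ValueError("R must have shape (N, 3, 3)")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 1e-9:
            raise ValueError("time grid must be uniform to within 1e-9 s")
        RtR = np.einsum("nij,nkj->nik", self.R, self.R)
        if np.max(np.abs(RtR - np.eye(3))) > 1e-9:
            raise ValueError("R contains non-orthonormal rotations")
        if np.any(np.linalg.det(self.R) < 0):
            raise ValueError("R contains improper rotations (det < 0)")

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def velocity_consistency(self) -> float:
        """Max norm of central-difference(p) − v on interior samples.

        O(dt) diagnostic, not enforced on construction: file-derived
        trajectories carry independently measured velocities.
        """
        fd = (self.p[2:] - self.p[:-2]) / (self.t[2:, None] - self.t[:-2, None])
        return float(np.max(np.linalg.norm(fd - self.v[1:-1], axis=1)))


@dataclass
class RelativeMotion:
    """Relative motion of a child frame, expressed in the parent frame.

    ``v_rel`` is the velocity of the child origin *as observed from the
    parent frame*, i.e. the parent-frame time derivative of ``r_rel``.
    """

    t: np.ndarray
    w_rel: np.ndarray
    v_rel: np.ndarray
    r_rel: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w_rel = _as_points(self.w_rel, "w_rel")
        self.v_rel = _as_points(self.v_rel, "v_rel")
        self.r_rel = _as_points(self.r_rel, "r_rel")
        n = self.t.shape[0]
        if any(a.shape[0] != n for a in (self.w_rel, self.v_rel, self.r_rel)):
            raise ValueError("t, w_rel, v_rel, r_rel must share length N")

    @property
    def n(self) -> int:
        return self.t.shape[0]


@dataclass
class AxisSampleSeries:
    """Per-step ICOR point and IAOR direction in the parent frame.

    ``c[i]`` is a point of momentarily zero perpendicular relative velocity;
    ``e[i]`` is the unit axis direction.  Steps where the relative angular
    speed falls below the singularity threshold carry ``valid[i] = False``
    and NaNs in ``c`` and ``e``.
    """

    t: np.ndarray
    c: np.ndarray
    e: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = _as_points(self.c, "c")
        self.e = _as_points(self.e, "e")
        if self.valid is None:
            self.valid = np.ones(self.t.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.shape[0]
        if any(a.shape[0] != n for a in (self.c, self.e, self.valid)):
            raise ValueError("t, c, e, valid must share length N")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


def relative_motion(parent: BodyTrajectory, child: BodyTrajectory) -> RelativeMotion:
    """Relative motion of ``child`` with respect to ``parent``.

    Per step, with :math:`R_p` the parent world-from-body rotation:

    .. math::

        r_{rel} &= R_p^\\top (p_c - p_p) \\\\
        \\omega_{rel} &= R_p^\\top (\\omega_c - \\omega_p) \\\\
        v_{rel} &= R_p^\\top [(v_c - v_p) - \\omega_p \\times (p_c - p_p)]

    the unique kinematically consistent choice making
    :math:`v_{rel} = \\frac{d}{dt} r_{rel}` in the parent frame.

    Raises
    ------
    GridMismatchError
        If the two trajectories are not sampled on the same time grid.
    """
    if parent.n != child.n or np.max(np.abs(parent.t - child.t)) > 1e-9:
        raise GridMismatchError("parent and child must share the time grid")
    dp = child.p - parent.p
    Rp_T = np.swapaxes(parent.R, 1, 2)
    r_rel = np.einsum("nij,nj->ni", Rp_T, dp)
    w_rel = np.einsum("nij,nj->ni", Rp_T, child.w - parent.w)
    v_world = child.v - parent.v - np.cross(parent.w, dp)
    v_rel = np.einsum("nij,nj->ni", Rp_T, v_world)
    return RelativeMotion(t=parent.t.copy(), w_rel=w_rel, v_rel=v_rel, r_rel=r_rel)


def icor_fixed_frame(w, v, r, eps_omega: float = EPS_OMEGA) -> np.ndarray:
    """ICOR of a single body relative to a fixed frame.

    .. math:: r_C = \\frac{\\omega \\times v}{\\lVert\\omega\\rVert^2} + r

    where ``r`` is any tracked point on the body, ``v`` its velocity and
    ``w`` the body's angular velocity, all in the fixed frame.  For planar
    motion the result is the unique zero-velocity point, independent of the
    choice of ``r``; in 3D it is one point on the instantaneous axis.

    Raises
    ------
    SingularSampleError
        If ``||w|| <= eps_omega`` (no rotation, center undefined).
    """
    w = np.asarray(w, dtype=float)
    v = np.asarray(v, dtype=float)
    r = np.asarray(r, dtype=float)
    n2 = float(w @ w)
    if np.sqrt(n2) <= eps_omega:
        raise SingularSampleError(
            f"|w| = {np.sqrt(n2):.3g} <= eps_omega = {eps_omega:.3g}"
        )
    return np.cross(w, v) / n2 + r


def axis_direction(w_rel, eps_omega: float = EPS_OMEGA) -> np.ndarray:
    """Unit direction of the instantaneous axis, ``w_rel / ||w_rel||``."""
    w_rel = np.asarray(w_rel, dtype=float)
    n = float(np.linalg.norm(w_rel))
    if n <= eps_omega:
        raise SingularSampleError(
            f"|w_rel| = {n:.3g} <= eps_omega = {eps_omega:.3g}"
        )
    return w_rel / n


def icor_relative(rm: RelativeMotion, eps_omega: float = EPS_OMEGA) -> AxisSampleSeries:
    """Per-step ICOR point and IAOR direction between two moving bodies.

    .. math:: c = \\frac{\\omega_{rel} \\times v_{rel}}
                       {\\lVert\\omega_{rel}\\rVert^2} + r_{rel},
              \\qquad e = \\frac{\\omega_{rel}}{\\lVert\\omega_{rel}\\rVert}

    Singular steps (``||w_rel|| <= eps_omega``) never raise; they are flagged
    invalid with NaN entries so the series stays aligned with the grid.
    """
    wn = np.linalg.norm(rm.w_rel, axis=1)
    valid = wn > eps_omega
    c = np.full_like(rm.r_rel, np.nan)
    e = np.full_like(rm.r_rel, np.nan)
    if np.any(valid):
        wv = rm.w_rel[valid]
        c[valid] = (
            np.cross(wv, rm.v_rel[valid]) / (wn[valid, None] ** 2)
            + rm.r_rel[valid]
        )
        e[valid] = wv / wn[valid, None]
    return AxisSampleSeries(t=rm.t.copy(), c=c, e=e, valid=valid)


def trajectory_from_poses(t, R, p) -> BodyTrajectory:
    """Build a :class:`BodyTrajectory` from poses only, with finite-difference
    velocities.

    Fallback for file input that carries no measured velocities.  Linear
    velocity is the central difference of ``p`` (one-sided at the ends);
    angular velocity comes from the skew part of :math:`\\dot R R^\\top`
    with :math:`\\dot R` finite-differenced the same way.  Both are O(dt²)
    accurate on interior samples for smooth motion.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)
    p = np.asarray(p, dtype=float)
    v = np.gradient(p, t, axis=0)
    Rdot = np.gradient(R, t, axis=0)
    W = np.einsum("nij,nkj->nik", Rdot, R)  # Rdot @ R^T, skew up to O(dt^2)
    w = np.stack(
        [
            0.5 * (W[:, 2, 1] - W[:, 1, 2]),
            0.5 * (W[:, 0, 2] - W[:, 2, 0]),
            0.5 * (W[:, 1, 0] - W[:, 0, 1]),
        ],
        axis=1,
    )
    return BodyTrajectory(t=t, R=R, p=p, v=v, w=w)
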