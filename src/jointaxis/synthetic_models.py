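"""Synthetic mechanism simulators with exact (analytic) sensor kinematics.

Three generators emulate the virtual-sensor studies used to verify the ICOR
method, each emitting a pair of :class:`~jointaxis.core_kinematics.BodyTrajectory`
sensor frames plus the generating mechanism's ground truth:

* :func:`double_pendulum` — planar two-link pendulum under gravity
  (Lagrangian dynamics of two uniform rods), revolute inter-body joint at
  the body-1 frame origin, one virtual IMU per link;
* :func:`ball_joint` — a fixed three-DoF rotation center (hip-like), driven
  by three Euler-angle waveforms, optionally with the parent segment itself
  moving;
* :func:`planar_custom_joint` — a knee-like joint whose child-frame origin
  follows cubic translation splines of the joint angle while rotating about
  the parent z-axis; the analytic moving ICOR is exposed as ground truth.

All generators produce *analytic* linear and angular velocities (no finite
differencing), so noisefree output exercises the ICOR formulas at machine
precision.  :func:`add_noise` corrupts velocity channels with white Gaussian
noise of stated variance, reproducibly under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .core_kinematics import BodyTrajectory

__all__ = [
    "Sinusoid",
    "sweep",
    "PendulumConfig",
    "BallJointConfig",
    "ParentExcursion",
    "SplineJointConfig",
    "NoiseSpec",
    "JointGroundTruth",
    "SimulationError",
    "double_pendulum",
    "ball_joint",
    "planar_custom_joint",
    "add_noise",
    "DEFAULT_KNEE_KNOTS",
]

_G_DEFAULT = 9.80665  # standard gravity, m/s^2


class SimulationError(RuntimeError):
    """Forward integration failed to meet tolerance."""


def _rotz(a: np.ndarray) -> np.ndarray:
    """Stack of rotations about z for angles ``a`` (shape (N,) -> (N,3,3))."""
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def _rot_axis(axis: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rodrigues rotation about a fixed unit axis for each angle in ``a``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    a = np.asarray(a, dtype=float)
    s = np.sin(a)[:, None, None]
    c = np.cos(a)[:, None, None]
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


@dataclass(frozen=True)
class Sinusoid:
    """Angle waveform ``offset + amplitude * sin(2*pi*frequency*t + phase)``
    with an analytic derivative."""

    amplitude: float
    frequency: float  # Hz
    phase: float = 0.0  # rad
    offset: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.amplitude * np.sin(
            2.0 * np.pi * self.frequency * t + self.phase
        )

    def deriv(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi * self.frequency
        return self.amplitude * w * np.cos(w * t + self.phase)


def sweep(lo: float, hi: float, duration: float) -> Sinusoid:
    """Smooth there-and-back sweep lo -> hi -> lo over ``duration`` seconds.

    Implemented as ``mid - half_range * cos(2*pi*t/T)`` so the velocity
    vanishes smoothly at both ends — a squat-like excursion for a joint
    angle.
    """
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return Sinusoid(
        amplitude=-half, frequency=1.0 / duration, phase=0.5 * np.pi, offset=mid
    )


def _time_grid(duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs))
    return np.arange(n) / fs


@dataclass
class JointGroundTruth:
    """What the generating mechanism actually did.

    ``center_parent`` is the joint center expressed in the *parent sensor
    frame* (the frame all estimates live in).  For moving-center joints the
    translation spline ``b_of_phi`` and the analytic moving ICOR
    ``icor_of_phi`` are callables of the joint angle (rad), and ``phi`` is
    the simulated angle path.
    """

    kind: str  # 'revolute' | 'ball' | 'planar_custom'
    center_parent: Optional[np.ndarray] = None
    phi: Optional[np.ndarray] = None
    b_of_phi: Optional[Callable[[np.ndarray], np.ndarray]] = None
    icor_of_phi: Optional[Callable[[np.ndarray], np.ndarray]] = None
    child_start: Optional[np.ndarray] = None
    degenerate: bool = False
    notes: str = ""


# ---------------------------------------------------------------------------
# Double pendulum
# ---------------------------------------------------------------------------

@dataclass
class PendulumConfig:
    """Planar double pendulum of two uniform rods under gravity.

    ``q0 = (shoulder, elbow)`` are the initial pivot and inter-link angles in
    radians, measured from the hanging rest pose (elbow relative to link 1).
    One virtual IMU is rigidly attached to each link at ``imu_offset`` in the
    link frame; link frames sit at the links' distal ends with +y pointing
    back along the rod toward the proximal joint, so the inter-link joint is
    at the origin of the link-1 frame.
    """

    L1: float = 1.0
    L2: float = 1.0
    m1: float = 1.0
    m2: float = 1.0
    g: float = _G_DEFAULT
    q0: tuple[float, float] = (0.5 * np.pi, 0.0)
    qdot0: tuple[float, float] = (0.0, 0.0)
    duration: float = 10.0
    fs: float = 100.0
    imu_offset: tuple[float, float, float] = (0.1, 0.5, 0.0)
    rtol: float = 1e-10
    atol: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "m1", "m2", "duration", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _pendulum_rhs(cfg: PendulumConfig):
    L1, L2, m1, m2, g = cfg.L1, cfg.L2, cfg.m1, cfg.m2, cfg.g
    # uniform-rod inertia; absolute angles a1, a2 from downward vertical
    M11 = m1 * L1 * L1 / 3.0 + m2 * L1 * L1
    M22 = m2 * L2 * L2 / 3.0
    C = 0.5 * m2 * L1 * L2
    G1 = (0.5 * m1 + m2) * g * L1
    G2 = 0.5 * m2 * g * L2

    def rhs(_t, y):
        a1, a2, d1, d2 = y
        co = math.cos(a1 - a2)
        si = math.sin(a1 - a2)
        M12 = C * co
        b1 = -C * d2 * d2 * si - G1 * math.sin(a1)
        b2 = C * d1 * d1 * si - G2 * math.sin(a2)
        det = M11 * M22 - M12 * M12
        dd1 = (M22 * b1 - M12 * b2) / det
        dd2 = (M11 * b2 - M12 * b1) / det
        return (d1, d2, dd1, dd2)

    return rhs


def pendulum_energy(cfg: PendulumConfig, y: np.ndarray) -> np.ndarray:
    """Total mechanical energy for states ``y = (a1, a2, a1dot, a2dot)``
    (rows), with potential zero at the hanging pose of each rod's center."""
    L1, L2, m1, m2, g = cfg.L1, cfg.L2, cfg.m1, cfg.m2, cfg.g
    a1, a2, d1, d2 = y.T
    T = (
        0.5 * (m1 * L1 * L1 / 3.0) * d1 * d1
        + 0.5 * m2 * (L1 * L1 * d1 * d1 + (L2 * L2 / 3.0) * d2 * d2)
        + 0.5 * m2 * L1 * L2 * d1 * d2 * np.cos(a1 - a2)
    )
    V = -(0.5 * m1 + m2) * g * L1 * np.cos(a1) - 0.5 * m2 * g * L2 * np.cos(a2)
    return T + V


def double_pendulum(
    cfg: Optional[PendulumConfig] = None,
) -> tuple[BodyTrajectory, BodyTrajectory, JointGroundTruth]:
    """Forward-simulate the pendulum and emit the two virtual-IMU trajectories.

    Gravity is the only external load.  The returned ground truth locates
    the inter-link revolute joint — the link-1 frame origin — in the parent
    sensor frame (i.e. at ``-imu_offset``, the sensor frames sharing the link
    frames' orientation).  Velocities are analytic functions of the
    integrated state, so a noisefree run drives the ICOR formulas at the
    integrator's accuracy.
    """
    cfg = cfg or PendulumConfig()
    t = _time_grid(cfg.duration, cfg.fs)
    a1_0 = cfg.q0[0]
    a2_0 = cfg.q0[0] + cfg.q0[1]  # elbow angle is relative to link 1
    d1_0 = cfg.qdot0[0]
    d2_0 = cfg.qdot0[0] + cfg.qdot0[1]
    sol = solve_ivp(
        _pendulum_rhs(cfg),
        (0.0, float(t[-1])) if t[-1] > 0 else (0.0, 1.0 / cfg.fs),
        (a1_0, a2_0, d1_0, d2_0),
        t_eval=t,
        method="DOP853",
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol.success:
        raise SimulationError(sol.message)
    a1, a2, d1, d2 = sol.y
    off = np.asarray(cfg.imu_offset, dtype=float)

    def link_traj(a, d, origin, v_origin):
        R = _rotz(a)
        p = origin + np.einsum("nij,j->ni", R, off)
        w = np.zeros((t.size, 3))
        w[:, 2] = d
        v = v_origin + np.cross(w, np.einsum("nij,j->ni", R, off))
        return BodyTrajectory(t=t, R=R, p=p, v=v, w=w)

    # link-1 frame origin = elbow; pivot at world origin
    elbow = np.stack(
        [cfg.L1 * np.sin(a1), -cfg.L1 * np.cos(a1), np.zeros_like(a1)], axis=1
    )
    v_elbow = np.stack(
        [cfg.L1 * d1 * np.cos(a1), cfg.L1 * d1 * np.sin(a1), np.zeros_like(a1)],
        axis=1,
    )
    # link-2 frame origin = free end of link 2
    tip = elbow + np.stack(
        [cfg.L2 * np.sin(a2), -cfg.L2 * np.cos(a2), np.zeros_like(a2)], axis=1
    )
    v_tip = v_elbow + np.stack(
        [cfg.L2 * d2 * np.cos(a2), cfg.L2 * d2 * np.sin(a2), np.zeros_like(a2)],
        axis=1,
    )
    parent = link_traj(a1, d1, elbow, v_elbow)
    child = link_traj(a2, d2, tip, v_tip)
    truth = JointGroundTruth(
        kind="revolute",
        center_parent=-off,
        phi=a2 - a1,
        notes="inter-link joint at the link-1 frame origin; center given in "
        "the parent sensor frame (sensor offset from the link frame).",
    )
    truth.states = np.stack([a1, a2, d1, d2], axis=1)  # for energy checks
    return parent, child, truth


# ---------------------------------------------------------------------------
# Ball joint (hip-like)
# ---------------------------------------------------------------------------

@dataclass
class ParentExcursion:
    """Rigid self-motion of the parent segment: sinusoidal translation along
    each world axis plus a sinusoidal rotation about a fixed world axis."""

    translation: tuple[Sinusoid, Sinusoid, Sinusoid]
    rotation: Sinusoid = Sinusoid(0.0, 0.0)
    rot_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class BallJointConfig:
    """Three-DoF rotation about a center fixed in the parent frame.

    The child frame's orientation relative to the parent is the intrinsic
    x-y-z composition ``Rx(a) @ Ry(b) @ Rz(c)`` of the three Euler waveforms;
    the child sensor origin sits at ``child_imu_offset`` from the center,
    rigid in the child frame.  Defaults emulate a squat-like hip excursion:
    a large flexion sweep plus smaller out-of-plane components, pelvis
    (parent) gently moving as well.
    """

    center_in_parent: tuple[float, float, float] = (-0.05, 0.25, -0.02)
    euler: tuple[Sinusoid, Sinusoid, Sinusoid] = (
        Sinusoid(0.30, 0.25),                      # ab/adduction-like, rad
        Sinusoid(0.20, 0.35, phase=1.0),           # internal rotation-like
        sweep(0.0, 1.6, 10.0 / 3.0),               # flexion: 3 cycles
    )
    fs: float = 100.0
    duration: float = 10.0
    child_imu_offset: tuple[float, float, float] = (0.05, -0.25, 0.02)
    parent_excursion: Optional[ParentExcursion] = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


def default_squat_parent_excursion() -> ParentExcursion:
    """A gentle pelvis-like excursion: a few cm of translation and a small
    tilt, so both joint partners move."""
    return ParentExcursion(
        translation=(
            Sinusoid(0.03, 0.2),
            Sinusoid(0.20, 0.1, phase=0.5 * np.pi, offset=-0.20),
            Sinusoid(0.02, 0.25, phase=0.7),
        ),
        rotation=Sinusoid(0.15, 0.2, phase=0.3),
        rot_axis=(1.0, 0.0, 0.0),
    )


def _euler_xyz_rotation(a, b, c):
    """Intrinsic Rx(a) @ Ry(b) @ Rz(c) per step, plus the three axis stacks
    needed for the analytic angular velocity."""
    Rx = _rot_axis(np.array([1.0, 0.0, 0.0]), a)
    Ry = _rot_axis(np.array([0.0, 1.0, 0.0]), b)
    Rz = _rotz(c)
    return Rx @ Ry @ Rz, Rx, Ry


def ball_joint(
    cfg: Optional[BallJointConfig] = None,
) -> tuple[BodyTrajectory, BodyTrajectory, JointGroundTruth]:
    """Simulate rotation about a fixed center (hip-like ball joint).

    Every relative-motion IAOR of the output passes through
    ``center_in_parent``; with fewer than two independent rotation axes the
    intersection point is not unique and the ground truth is flagged
    ``degenerate``.
    """
    cfg = cfg or BallJointConfig()
    t = _time_grid(cfg.duration, cfg.fs)
    n = t.size
    wa, wb, wc = cfg.euler
    a, b, c = wa(t), wb(t), wc(t)
    da, db, dc = wa.deriv(t), wb.deriv(t), wc.deriv(t)
    R_rel, Rx, Ry = _euler_xyz_rotation(a, b, c)
    # omega of Rx(a)Ry(b)Rz(c) expressed in the parent frame:
    #   w = a' x_hat + b' Rx y_hat + c' Rx Ry z_hat
    w_rel = (
        da[:, None] * np.array([1.0, 0.0, 0.0])
        + db[:, None] * Rx[:, :, 1]
        + dc[:, None] * (Rx @ Ry)[:, :, 2]
    )
    center = np.asarray(cfg.center_in_parent, dtype=float)
    r0 = np.asarray(cfg.child_imu_offset, dtype=float)
    # child origin in parent frame and its parent-frame derivative
    arm = np.einsum("nij,j->ni", R_rel, r0)
    r_cp = center + arm
    dr_cp = np.cross(w_rel, arm)

    if cfg.parent_excursion is None:
        Rp = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        pp = np.zeros((n, 3))
        vp = np.zeros((n, 3))
        wp = np.zeros((n, 3))
    else:
        ex = cfg.parent_excursion
        axis = np.asarray(ex.rot_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        Rp = _rot_axis(axis, ex.rotation(t))
        pp = np.stack([s(t) for s in ex.translation], axis=1)
        vp = np.stack([s.deriv(t) for s in ex.translation], axis=1)
        wp = ex.rotation.deriv(t)[:, None] * axis

    parent = BodyTrajectory(t=t, R=Rp, p=pp, v=vp, w=wp)
    Rc = Rp @ R_rel
    pc = pp + np.einsum("nij,nj->ni", Rp, r_cp)
    vc = vp + np.cross(wp, np.einsum("nij,nj->ni", Rp, r_cp)) + np.einsum(
        "nij,nj->ni", Rp, dr_cp
    )
    wc_world = wp + np.einsum("nij,nj->ni", Rp, w_rel)
    child = BodyTrajectory(t=t, R=Rc, p=pc, v=vc, w=wc_world)

    # degenerate iff the relative rotation stays about one fixed axis
    norms = np.linalg.norm(w_rel, axis=1)
    active = norms > 1e-12
    degenerate = True
    if np.count_nonzero(active) >= 2:
        dirs = w_rel[active] / norms[active, None]
        degenerate = bool(
            np.all(np.abs(np.abs(dirs @ dirs[0]) - 1.0) < 1e-9)
        )
    truth = JointGroundTruth(
        kind="ball",
        center_parent=center,
        degenerate=degenerate,
        notes="center fixed in the parent sensor frame"
        + ("; DEGENERATE: single rotation axis, intersection not unique"
           if degenerate else ""),
    )
    return parent, child, truth


# ---------------------------------------------------------------------------
# Planar custom joint (knee-like)
# ---------------------------------------------------------------------------

# Default tibiofemoral-like knot table: child-origin translation in the
# parent (femur) frame as a function of flexion angle (rad, flexion
# positive).  A few mm of anterior-posterior (x) excursion and a distal (y)
# drop of ~2.7 cm over 0-120 deg, steepening in deep flexion — the scale and
# qualitative shape generic full-body models prescribe for a rolling-
# gliding knee.  Any user table may replace it.
DEFAULT_KNEE_KNOTS: tuple[tuple[float, float, float], ...] = (
    (-0.175, 0.0045, -0.3958),
    (0.0, 0.0041, -0.3960),
    (0.35, 0.0021, -0.3976),
    (0.70, -0.0010, -0.3996),
    (1.05, -0.0031, -0.4022),
    (1.40, -0.0047, -0.4060),
    (1.75, -0.0055, -0.4110),
    (2.20, -0.0049, -0.4226),
)


@dataclass
class SplineJointConfig:
    """One rotational + two translational DoF, translations slaved to angle.

    ``knots`` are ``(phi, x, y)`` rows (rad, m, m) interpolated by cubic
    splines; the child frame rotates by ``phi(t)`` about the parent z-axis
    while its origin follows ``(x(phi), y(phi))``.  ``phi(t)`` must stay
    inside the knot range.  If ``child_start`` is given, the translation
    splines are shifted so the child origin sits exactly there at phi = 0.
    """

    knots: Sequence[tuple[float, float, float]] = DEFAULT_KNEE_KNOTS
    angle_trajectory: Sinusoid = field(
        default_factory=lambda: sweep(math.radians(-5.0), math.radians(120.0), 10.0)
    )
    fs: float = 100.0
    duration: float = 10.0
    child_start: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        phis = np.array([k[0] for k in self.knots], dtype=float)
        if phis.size < 2 or np.any(np.diff(phis) <= 0):
            raise ValueError("knot angles must be strictly increasing")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


def _knee_splines(cfg: SplineJointConfig):
    k = np.asarray(cfg.knots, dtype=float)
    xy = k[:, 1:3].copy()
    if cfg.child_start is not None:
        base = np.array(
            [CubicSpline(k[:, 0], xy[:, j])(0.0) for j in range(2)]
        )
        xy += np.asarray(cfg.child_start, dtype=float) - base
    return CubicSpline(k[:, 0], xy, axis=0), (float(k[0, 0]), float(k[-1, 0]))


def planar_custom_joint(
    cfg: Optional[SplineJointConfig] = None,
) -> tuple[BodyTrajectory, BodyTrajectory, JointGroundTruth]:
    """Simulate a knee-like planar custom joint.

    The moving ICOR of the generated motion is, analytically,

    .. math:: c(\\phi) = b(\\phi) + \\hat z \\times \\frac{db}{d\\phi}

    where :math:`b(\\phi)` is the spline translation of the child origin in
    the parent frame; both are exposed through the ground truth.  The parent
    is held at the world identity pose (relative motion, the only input to
    the method, is unaffected by common rigid motion).
    """
    cfg = cfg or SplineJointConfig()
    t = _time_grid(cfg.duration, cfg.fs)
    n = t.size
    spl, (lo, hi) = _knee_splines(cfg)
    phi = cfg.angle_trajectory(t)
    if phi.min() < lo - 1e-12 or phi.max() > hi + 1e-12:
        raise ValueError(
            f"phi(t) range [{phi.min():.4f}, {phi.max():.4f}] rad exceeds "
            f"knot range [{lo:.4f}, {hi:.4f}]"
        )
    dphi = cfg.angle_trajectory.deriv(t)
    b = np.zeros((n, 3))
    b[:, :2] = spl(phi)
    db = np.zeros((n, 3))
    db[:, :2] = spl(phi, 1)

    parent = BodyTrajectory(
        t=t,
        R=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        p=np.zeros((n, 3)),
        v=np.zeros((n, 3)),
        w=np.zeros((n, 3)),
    )
    w = np.zeros((n, 3))
    w[:, 2] = dphi
    child = BodyTrajectory(
        t=t, R=_rotz(phi), p=b, v=dphi[:, None] * db, w=w
    )

    def b_of_phi(ph):
        ph = np.asarray(ph, dtype=float)
        out = np.zeros(ph.shape + (3,))
        out[..., :2] = spl(ph)
        return out

    def icor_of_phi(ph):
        ph = np.asarray(ph, dtype=float)
        bb = spl(ph)
        dd = spl(ph, 1)
        out = np.zeros(ph.shape + (3,))
        out[..., 0] = bb[..., 0] - dd[..., 1]  # x - dy/dphi
        out[..., 1] = bb[..., 1] + dd[..., 0]  # y + dx/dphi
        return out

    truth = JointGroundTruth(
        kind="planar_custom",
        phi=phi,
        b_of_phi=b_of_phi,
        icor_of_phi=icor_of_phi,
        child_start=b_of_phi(0.0),
        notes="moving ICOR c(phi) = b(phi) + z x db/dphi in the parent frame",
    )
    return parent, child, truth


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian noise on the velocity channels.

    ``var_linear`` and ``var_angular`` are *variances* — N(0, sigma^2) with
    sigma^2 as stated — applied i.i.d. per component per step to ``v`` and
    ``w``.  Poses (``t``, ``R``, ``p``) are left untouched.
    """

    var_linear: float = 0.0
    var_angular: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.var_linear < 0 or self.var_angular < 0:
            raise ValueError("variances must be non-negative")


def add_noise(traj: BodyTrajectory, spec: NoiseSpec) -> BodyTrajectory:
    """Return a copy of ``traj`` with noisy velocity channels (reproducible
    under ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    v = traj.v + rng.normal(0.0, math.sqrt(spec.var_linear), traj.v.shape)
    w = traj.w + rng.normal(0.0, math.sqrt(spec.var_angular), traj.w.shape)
    return BodyTrajectory(
        t=traj.t.copy(), R=traj.R.copy(), p=traj.p.copy(), v=v, w=w
    )
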