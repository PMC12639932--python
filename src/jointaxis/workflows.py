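"""End-to-end study workflows: simulate → corrupt → estimate → evaluate.

Thin compositions of the generator, denoising and estimator layers that
produce the condition-by-metric tables for the three synthetic joints
(pendulum revolute, hip ball, knee planar custom).  Each workflow takes one
integer seed and derives per-body noise streams from it, so a run is fully
reproducible.

Default study conditions: 100 Hz sampling, 10 s records (1000 samples),
white Gaussian velocity noise with standard deviations 0.1 m/s / 0.01 rad/s
for the pendulum and 0.02 for both channels of the musculoskeletal joints,
moving-average window 10, Butterworth order 2 (pendulum) or 3 (knee) at
5 Hz cutoff, knee smoothing parameters (3e-5, 0.003) with a ±1 cm margin.
The knee study drives the joint through a calibration-style trial of three
squat cycles (−5° to 120° flexion and back per cycle).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core_kinematics import icor_relative, relative_motion
from .denoise import FilterSpec
from .estimators import (
    fixed_center_lsq,
    knee_moving_axis,
    pearson_on_grid,
    planar_fixed_center,
    reconstruct_child_path,
)
from .synthetic_models import (
    BallJointConfig,
    NoiseSpec,
    PendulumConfig,
    Sinusoid,
    SplineJointConfig,
    add_noise,
    ball_joint,
    default_squat_parent_excursion,
    double_pendulum,
    planar_custom_joint,
)

__all__ = [
    "PENDULUM_NOISE",
    "MSK_NOISE",
    "noisy_pair",
    "pendulum_table",
    "knee_study",
    "knee_study_config",
    "knee_recovery",
    "knee_recovery_median",
    "hip_study",
    "hip_recovery_median",
]

#: (var_linear, var_angular) used in the two studies, (m/s)^2 and (rad/s)^2.
#: The study noise levels (0.1 / 0.01 for the pendulum, 0.02 / 0.02 for the
#: musculoskeletal joints) are standard deviations of the added Gaussian
#: perturbations; NoiseSpec stores variances, hence the squares.
PENDULUM_NOISE = (0.1**2, 0.01**2)
MSK_NOISE = (0.02**2, 0.02**2)


def noisy_pair(parent, child, variances, seed: int):
    """Corrupt both bodies' velocities with independent noise streams
    derived from one seed."""
    vl, va = variances
    s1, s2 = (
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    return (
        add_noise(parent, NoiseSpec(vl, va, seed=s1)),
        add_noise(child, NoiseSpec(vl, va, seed=s2)),
    )


def knee_study_config(n_cycles: int = 3, duration: float = 10.0) -> SplineJointConfig:
    """Calibration-style knee trial: repeated squat cycles (−5° to 120°
    flexion and back), ``n_cycles`` in ``duration`` seconds at 100 Hz.

    Repetitions spread the samples over the angle range several times,
    which is what functional joint-calibration protocols do to condition
    the estimate.
    """
    lo, hi = np.deg2rad(-5.0), np.deg2rad(120.0)
    traj = Sinusoid(
        amplitude=-0.5 * (hi - lo),
        frequency=n_cycles / duration,
        phase=0.5 * np.pi,
        offset=0.5 * (lo + hi),
    )
    return SplineJointConfig(angle_trajectory=traj, duration=duration, fs=100.0)


def _knee_filter(fs: float) -> dict[str, FilterSpec]:
    return {
        "MA-WO": FilterSpec("moving_average", window=10, fs=fs),
        "BW-WO": FilterSpec("butterworth", order=3, cutoff=5.0, fs=fs),
    }


def pendulum_table(
    seed: int = 1, cfg: Optional[PendulumConfig] = None
) -> pd.DataFrame:
    """Pendulum ICOR statistics per condition (mean/median/RMSE per
    coordinate of the deviation from the known revolute center).

    Conditions: ``noisefree``; ``noisy`` (raw, no outlier removal);
    ``MA-WO`` and ``BW-WO`` (1.5-IQR outlier removal, then moving-average
    window 10 or zero-phase Butterworth order 2 at 5 Hz).
    """
    cfg = cfg or PendulumConfig()
    parent, child, truth = double_pendulum(cfg)
    axes_clean = icor_relative(relative_motion(parent, child))
    np_, nc = noisy_pair(parent, child, PENDULUM_NOISE, seed)
    axes_noisy = icor_relative(relative_motion(np_, nc))
    rows = []

    def add_row(cond, dev):
        rows.append(
            {
                "condition": cond,
                "n": dev.shape[0],
                "mean_x": dev[:, 0].mean(),
                "mean_y": dev[:, 1].mean(),
                "median_x": np.median(dev[:, 0]),
                "median_y": np.median(dev[:, 1]),
                "rmse_x": np.sqrt(np.mean(dev[:, 0] ** 2)),
                "rmse_y": np.sqrt(np.mean(dev[:, 1] ** 2)),
            }
        )

    truth_xy = truth.center_parent[:2]
    add_row("noisefree", axes_clean.c[axes_clean.valid][:, :2] - truth_xy)
    add_row("noisy", axes_noisy.c[axes_noisy.valid][:, :2] - truth_xy)
    for cond, fspec in (
        ("MA-WO", FilterSpec("moving_average", window=10, fs=cfg.fs)),
        ("BW-WO", FilterSpec("butterworth", order=2, cutoff=5.0, fs=cfg.fs)),
    ):
        rep = planar_fixed_center(axes_noisy, truth.center_parent, fspec)
        add_row(cond, rep.series)
        rows[-1]["n"] = rep.n_retained
    return pd.DataFrame(rows)


def _knee_axes(cfg: SplineJointConfig, seed: Optional[int]):
    parent, child, truth = planar_custom_joint(cfg)
    if seed is not None:
        parent, child = noisy_pair(parent, child, MSK_NOISE, seed)
    axes = icor_relative(relative_motion(parent, child))
    return axes, truth


def knee_study(
    seed: int = 1, cfg: Optional[SplineJointConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Knee pipeline for one noise realization.

    Returns ``(correlations, reconstruction)``: Pearson r between the
    smoothed and true center curves per coordinate and filter (201-point
    common grid), and per-coordinate RMSE between the true child path and
    the path reconstructed from the estimated moving center.
    """
    cfg = cfg or knee_study_config()
    axes, truth = _knee_axes(cfg, seed)
    corr_rows, recon_rows = [], []
    for cond, fspec in _knee_filter(cfg.fs).items():
        curve = knee_moving_axis(axes, truth.phi, filter_spec=fspec)
        lo, hi = curve.domain
        corr_rows.append(
            {
                "condition": cond,
                "r_x": pearson_on_grid(
                    curve.cx, lambda p: truth.icor_of_phi(p)[..., 0], lo, hi
                ),
                "r_y": pearson_on_grid(
                    curve.cy, lambda p: truth.icor_of_phi(p)[..., 1], lo, hi
                ),
            }
        )
        b_true = truth.b_of_phi(truth.phi)
        path = reconstruct_child_path(curve, truth.phi, b_true[0])
        err = path.b[:, :2] - b_true[:, :2]
        recon_rows.append(
            {
                "condition": cond,
                "rmse_x": np.sqrt(np.mean(err[:, 0] ** 2)),
                "rmse_y": np.sqrt(np.mean(err[:, 1] ** 2)),
            }
        )
    return pd.DataFrame(corr_rows), pd.DataFrame(recon_rows)


def knee_recovery(
    seed: int, cfg: Optional[SplineJointConfig] = None
) -> pd.DataFrame:
    """Reconstruction RMSE per coordinate and filter for one noise seed."""
    _, recon = knee_study(seed=seed, cfg=cfg)
    return recon


def knee_recovery_median(
    seed: int = 1, n_seeds: int = 20, cfg: Optional[SplineJointConfig] = None
) -> pd.DataFrame:
    """Median over noise seeds of the knee reconstruction RMSE.

    One row per (filter, coordinate); RMSE in meters.  Seeds are spawned
    from ``seed`` so the whole study is reproducible from one integer.
    """
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_seeds)]
    frames = [knee_recovery(s, cfg=cfg) for s in seeds]
    allruns = pd.concat(frames, ignore_index=True)
    return (
        allruns.groupby("condition", sort=False)[["rmse_x", "rmse_y"]]
        .median()
        .reset_index()
    )


def hip_study(
    seed: int = 1, cfg: Optional[BallJointConfig] = None
) -> pd.DataFrame:
    """Hip (ball joint) center estimation for one noise realization.

    Both parent and child move; every valid noisy axis feeds the least-
    squares intersection, with no prior filtering.
    """
    if cfg is None:
        cfg = BallJointConfig(parent_excursion=default_squat_parent_excursion())
    parent, child, truth = ball_joint(cfg)
    clean_axes = icor_relative(relative_motion(parent, child))
    np_, nc = noisy_pair(parent, child, MSK_NOISE, seed)
    axes = icor_relative(relative_motion(np_, nc))
    rows = []
    for cond, ax in (("noisefree", clean_axes), ("noisy", axes)):
        est = fixed_center_lsq(ax)
        rows.append(
            {
                "condition": cond,
                "x": est.point[0],
                "y": est.point[1],
                "z": est.point[2],
                "error_mm": np.linalg.norm(est.point - truth.center_parent) * 1e3,
                "rms_line_distance": est.rms_line_distance,
                "n_axes": est.n_lines,
            }
        )
    return pd.DataFrame(rows)


def hip_recovery_median(
    seed: int = 1, n_seeds: int = 20, cfg: Optional[BallJointConfig] = None
) -> float:
    """Median over noise seeds of the hip-center recovery error, meters."""
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_seeds)]
    errs = [
        hip_study(seed=s, cfg=cfg).set_index("condition").loc["noisy", "error_mm"]
        / 1e3
        for s in seeds
    ]
    return float(np.median(errs))
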