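"""Joint-model estimation from per-step ICOR/IAOR samples.

Three joint archetypes are covered, mirroring how fixed and moving rotation
centers appear in musculoskeletal models:

* a planar fixed center (revolute, pendulum-style): IQR outlier removal +
  time filtering of the ICOR coordinates, then per-coordinate statistics
  against the known center;
* a 3D fixed center (ball joint, hip-style): the point of least summed
  squared perpendicular distance to all instantaneous axes;
* a moving center slaved to the joint angle (knee-style): smoothing-spline
  denoising of the ICOR coordinates over the angle, then marching the child
  frame along the estimated center curve to reconstruct the child's
  translation path in the parent frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core_kinematics import AxisSampleSeries
from .denoise import (
    FilterSpec,
    SmoothingSplineSpec,
    apply_filter,
    iqr_outlier_mask,
    smoothing_spline,
    spline_margin_outliers,
)

__all__ = [
    "DegenerateGeometryError",
    "EstimationError",
    "FixedCenterEstimate",
    "PlanarCenterReport",
    "MovingAxisCurve",
    "ChildPath",
    "EstimationReport",
    "fixed_center_lsq",
    "planar_fixed_center",
    "knee_moving_axis",
    "reconstruct_child_path",
    "metrics",
    "pearson_on_grid",
    "KNEE_SPLINE_SPECS",
]


class DegenerateGeometryError(ValueError):
    """Axis geometry does not pin down a unique point (e.g. parallel axes)."""


class EstimationError(RuntimeError):
    """Estimation pipeline could not produce a usable result."""


#: Default smoothing parameters for the knee pipeline's (x, y) ICOR
#: coordinates (csaps convention) with the ±1 cm outlier margin.  The x
#: translation curve is gentle and takes heavy smoothing; the y curve has
#: more structure and needs a larger p.
KNEE_SPLINE_SPECS: tuple[SmoothingSplineSpec, SmoothingSplineSpec] = (
    SmoothingSplineSpec(p=3e-5, margin=0.01),
    SmoothingSplineSpec(p=0.003, margin=0.01),
)


@dataclass
class FixedCenterEstimate:
    """Least-squares intersection of a bundle of instantaneous axes."""

    point: np.ndarray
    rms_line_distance: float
    n_lines: int


@dataclass
class PlanarCenterReport:
    """Per-coordinate deviation statistics of a planar ICOR series against a
    known fixed center, after outlier removal and optional filtering."""

    mean: np.ndarray
    median: np.ndarray
    rmse: np.ndarray
    n_retained: int
    retained: np.ndarray  # mask over the full series
    series: np.ndarray  # filtered (x, y) deviations actually scored


@dataclass
class MovingAxisCurve:
    """Smoothed moving-center curve c(phi) = (cx(phi), cy(phi), 0)."""

    phi_grid: np.ndarray
    cx: Callable[[np.ndarray], np.ndarray]
    cy: Callable[[np.ndarray], np.ndarray]
    source_mask: np.ndarray  # True where a sample survived per-coord rejection

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.phi_grid[0]), float(self.phi_grid[-1])

    def __call__(self, phi) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        out = np.zeros(phi.shape + (3,))
        out[..., 0] = self.cx(phi)
        out[..., 1] = self.cy(phi)
        return out


@dataclass
class ChildPath:
    """Child-frame origin positions in the parent frame along an angle path."""

    phi: np.ndarray
    b: np.ndarray


@dataclass
class EstimationReport:
    """Per-coordinate mean/median/RMSE of (estimate − truth) and Pearson r.

    ``pearson_r`` is NaN for a coordinate whose estimate or truth has zero
    variance (correlation undefined).
    """

    mean: np.ndarray
    median: np.ndarray
    rmse: np.ndarray
    pearson_r: np.ndarray


# ---------------------------------------------------------------------------
# Fixed centers
# ---------------------------------------------------------------------------

def fixed_center_lsq(axes: AxisSampleSeries) -> FixedCenterEstimate:
    """Point minimizing the summed squared perpendicular distance to all
    valid instantaneous axes.

    Solves the normal equations ``sum_i (I - e_i e_i^T) x = sum_i
    (I - e_i e_i^T) c_i`` — each term projects out the axis direction, so a
    point exactly on every line zeroes the residual.

    Raises
    ------
    DegenerateGeometryError
        With fewer than 2 valid axes, or all axes (anti)parallel: the
        intersection point is not unique along the common direction.
    """
    c = axes.c[axes.valid]
    e = axes.e[axes.valid]
    if c.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 valid axes")
    P = np.eye(3)[None] - np.einsum("ni,nj->nij", e, e)
    A = P.sum(axis=0)
    rhs = np.einsum("nij,nj->i", P, c)
    # all-parallel bundles leave a null direction in A
    evals = np.linalg.eigvalsh(A)
    if evals[0] <= 1e-9 * max(evals[-1], 1.0):
        raise DegenerateGeometryError(
            "axes are parallel within tolerance; intersection point is "
            "undetermined along the common direction"
        )
    x = np.linalg.solve(A, rhs)
    d = x - c
    perp = d - np.einsum("ni,ni->n", d, e)[:, None] * e
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return FixedCenterEstimate(point=x, rms_line_distance=rms, n_lines=c.shape[0])


def planar_fixed_center(
    axes: AxisSampleSeries,
    truth_point,
    filter_spec: Optional[FilterSpec] = None,
) -> PlanarCenterReport:
    """Score a planar fixed-center ICOR series against a known center.

    Pipeline: drop invalid samples, apply the 1.5-IQR rule per coordinate
    (a sample is removed if either coordinate is flagged), optionally
    low-pass filter each retained coordinate as a time series, then report
    per-coordinate mean, median and RMSE of the deviation from
    ``truth_point``.
    """
    truth = np.asarray(truth_point, dtype=float)[:2]
    retained = axes.valid.copy()
    xy = axes.c[:, :2]
    for j in range(2):
        col = np.where(retained, xy[:, j], np.nan)
        try:
            mask, _ = iqr_outlier_mask(col)
        except ValueError as exc:
            raise EstimationError("too few valid samples for the IQR rule") from exc
        retained &= ~mask
    dev = xy[retained] - truth
    if filter_spec is not None:
        dev = np.stack(
            [apply_filter(dev[:, j], filter_spec) for j in range(2)], axis=1
        )
    return PlanarCenterReport(
        mean=dev.mean(axis=0),
        median=np.median(dev, axis=0),
        rmse=np.sqrt(np.mean(dev**2, axis=0)),
        n_retained=int(np.count_nonzero(retained)),
        retained=retained,
        series=dev,
    )


# ---------------------------------------------------------------------------
# Moving center (knee)
# ---------------------------------------------------------------------------

def _as_specs(
    spec: Union[SmoothingSplineSpec, Sequence[SmoothingSplineSpec], None],
) -> tuple[SmoothingSplineSpec, SmoothingSplineSpec]:
    if spec is None:
        return KNEE_SPLINE_SPECS
    if isinstance(spec, SmoothingSplineSpec):
        return (spec, spec)
    sx, sy = spec
    return (sx, sy)


def knee_moving_axis(
    axes: AxisSampleSeries,
    phi,
    spec: Union[SmoothingSplineSpec, Sequence[SmoothingSplineSpec], None] = None,
    filter_spec: Optional[FilterSpec] = None,
    pre_exclusion: Union[str, float, None] = "iqr",
    grid_points: int = 201,
) -> MovingAxisCurve:
    """Estimate the moving-center curve c(phi) of a planar custom joint.

    Pipeline, per coordinate: gross pre-exclusion, smoothing-spline fit over
    phi with rejection of samples outside ``±margin`` of the fit, low-pass
    filtering of the retained samples in time order, and a final smoothing
    spline of the filtered values over phi.

    ``pre_exclusion`` guards the first spline fit against the heavy tail of
    near-singular ICOR samples (values reach hundreds of meters where the
    relative rotation rate dips; an unprotected least-squares fit lands
    meters from the data's central mass and the ±margin band then retains
    nothing).  ``"iqr"`` (default) applies the 1.5-IQR rule per coordinate,
    a float is an absolute coordinate bound in meters, ``None`` disables the
    guard.

    ``spec`` may be one :class:`SmoothingSplineSpec` for both coordinates or
    a pair (x, y); the default is the knee tuning ``p = (3e-5, 0.003)``,
    margin ±1 cm.  Fewer than 10 retained samples in either coordinate is an
    :class:`EstimationError`.

    The smoothing splines are fit with the angle expressed in *degrees*:
    the default smoothing parameters are calibrated for that abscissa scale
    (an equivalent λ scales with the cube of the abscissa unit, so the same
    p over radians would stiffen the fit by (180/π)³ ≈ 1.9e5 and flatten
    the curve to a line).  The returned curve still takes radians.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] != axes.t.shape[0]:
        raise ValueError("phi and axes must share the time grid")
    if np.ptp(phi[np.isfinite(phi)]) < np.deg2rad(20.0):
        raise ValueError("phi range must span more than 20 degrees")
    sx, sy = _as_specs(spec)
    phi_deg = np.rad2deg(phi)
    base = axes.valid & np.all(np.isfinite(axes.c), axis=1)
    splines: list[Callable[[np.ndarray], np.ndarray]] = []
    masks = []
    lo, hi = -np.inf, np.inf
    for j, sj in enumerate((sx, sy)):
        keep = base.copy()
        col = axes.c[:, j]
        if pre_exclusion == "iqr":
            pre_mask, _ = iqr_outlier_mask(np.where(keep, col, np.nan))
            keep &= ~pre_mask
        elif pre_exclusion is not None:
            keep &= np.abs(col) <= float(pre_exclusion)
        y = np.where(keep, col, np.nan)
        out_mask, _ = spline_margin_outliers(phi_deg, y, sj.p, sj.margin)
        keep &= ~out_mask
        if np.count_nonzero(keep) < 10:
            raise EstimationError("fewer than 10 retained samples")
        # filter retained samples as a (time-ordered) series, then refit
        vals = col[keep]
        if filter_spec is not None:
            vals = apply_filter(vals, filter_spec)
        s_deg = smoothing_spline(phi_deg[keep], vals, sj.p)
        splines.append(lambda q, _s=s_deg: _s(np.rad2deg(q)))
        masks.append(keep)
        lo = max(lo, phi[keep].min())
        hi = min(hi, phi[keep].max())
    return MovingAxisCurve(
        phi_grid=np.linspace(lo, hi, grid_points),
        cx=splines[0],
        cy=splines[1],
        source_mask=masks[0] & masks[1],
    )


def reconstruct_child_path(
    curve: MovingAxisCurve, phi_path, b0
) -> ChildPath:
    """March the child origin along an angle path from a known start.

    Per step the child frame rotates by ``dphi = phi_n - phi_(n-1)`` about
    the parent z-axis around the step's rotation center — the midpoint of
    the curve's centers at the two angles:

        b_n = R(dphi) (b_(n-1) - c_n) + c_n,
        c_n = (c*(phi_n) + c*(phi_(n-1))) / 2.

    The march is exactly reversible (running the reversed path returns the
    start to round-off).  ``b0`` is the child origin at ``phi_path[0]``.
    """
    phi_path = np.asarray(phi_path, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    cs = curve(phi_path)  # c* at every path angle
    n = phi_path.shape[0]
    b = np.zeros((n, 3))
    b[0] = b0
    z = b0[0] + 1j * b0[1]
    for i in range(1, n):
        dphi = phi_path[i] - phi_path[i - 1]
        if dphi == 0.0:
            b[i] = b[i - 1]
            continue
        cm = 0.5 * (cs[i] + cs[i - 1])
        c = cm[0] + 1j * cm[1]
        z = np.exp(1j * dphi) * (z - c) + c
        b[i, 0] = z.real
        b[i, 1] = z.imag
        b[i, 2] = b[i - 1, 2]
    return ChildPath(phi=phi_path, b=b)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def metrics(estimate, truth) -> EstimationReport:
    """Per-coordinate mean, median, RMSE of (estimate − truth) and the
    Pearson correlation between the two series.

    Accepts (N,) or (N, k) arrays sampled on a shared grid.  Zero-variance
    coordinates yield ``pearson_r = NaN`` (undefined correlation).
    """
    est = np.atleast_2d(np.asarray(estimate, dtype=float).T).T
    tru = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    if est.shape != tru.shape:
        raise ValueError("estimate and truth must be aligned")
    diff = est - tru
    r = np.array([_pearson(est[:, j], tru[:, j]) for j in range(est.shape[1])])
    return EstimationReport(
        mean=diff.mean(axis=0),
        median=np.median(diff, axis=0),
        rmse=np.sqrt(np.mean(diff**2, axis=0)),
        pearson_r=r,
    )


def pearson_on_grid(
    f: Callable[[np.ndarray], np.ndarray],
    g: Callable[[np.ndarray], np.ndarray],
    lo: float,
    hi: float,
    n: int = 201,
) -> float:
    """Pearson correlation of two curves on a uniform grid over [lo, hi].

    Curves, not samples, are compared: both callables are evaluated on the
    same ``n``-point grid.
    """
    x = np.linspace(lo, hi, n)
    return _pearson(np.asarray(f(x), float), np.asarray(g(x), float))
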