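"""Noise compensation for ICOR coordinate series.

ICOR estimates computed from noisy velocity data are heavy-tailed: the
angular speed enters the formula squared in the denominator, so steps with
small rotation rates blow isolated samples up by orders of magnitude.  The
toolbox here is the sequence used to recover the underlying curves:

* :func:`iqr_outlier_mask` — the 1.5-IQR rule, per coordinate;
* :func:`moving_average` — NaN-aware centered moving average (window 10 by
  default);
* :func:`butterworth` — zero-phase low-pass Butterworth (order 2 or 3,
  5 Hz cutoff by default);
* :func:`smoothing_spline` — cubic smoothing spline in the csaps/MATLAB
  parameter convention, ``p * sum (y - s(x))^2 + (1 - p) * int (s'')^2``;
* :func:`spline_margin_outliers` — fit a smoothing spline, drop samples
  farther than a margin (±1 cm by default) from it, refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "FilterSpec",
    "SmoothingSplineSpec",
    "iqr_outlier_mask",
    "moving_average",
    "butterworth",
    "smoothing_spline",
    "spline_margin_outliers",
    "apply_filter",
]


@dataclass(frozen=True)
class FilterSpec:
    """A time-domain low-pass filter choice.

    ``moving_average`` uses ``window`` samples; ``butterworth`` uses
    ``order`` and ``cutoff`` (Hz) at sampling rate ``fs`` (Hz).
    """

    kind: Literal["moving_average", "butterworth"] = "moving_average"
    window: int = 10
    order: int = 2
    cutoff: float = 5.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 < self.cutoff < 0.5 * self.fs):
            raise ValueError("cutoff must lie in (0, fs/2)")


@dataclass(frozen=True)
class SmoothingSplineSpec:
    """Smoothing parameter (csaps convention) and outlier margin half-width.

    ``p = 1`` interpolates, ``p = 0`` gives the least-squares line; the
    margin is in the ordinate's units (meters for ICOR coordinates).
    """

    p: float = 0.003
    margin: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def iqr_outlier_mask(series) -> tuple[np.ndarray, tuple[float, float]]:
    """Flag values outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.

    Quartiles use linear interpolation between order statistics; NaNs are
    ignored when computing the bounds and flagged as outliers.  Returns
    ``(mask, (lower, upper))`` with ``mask`` True at outliers.  With fewer
    than 4 finite values the rule is ill-posed and a ValueError is raised.
    All-identical input degenerates to zero IQR: only exact-equal values
    are retained.
    """
    y = np.asarray(series, dtype=float)
    finite = np.isfinite(y)
    if np.count_nonzero(finite) < 4:
        raise ValueError("need at least 4 finite values for the IQR rule")
    q1, q3 = np.percentile(y[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = ~finite | (y < lo) | (y > hi)
    return mask, (float(lo), float(hi))


def moving_average(series, window: int = 10) -> np.ndarray:
    """NaN-aware centered moving average.

    The window is centered on each sample, split floor/ceil for even
    lengths (window 10: 5 before, 4 after, plus the sample).  Invalid
    (NaN) samples and samples beyond the ends are excluded from the window
    mean, so the output has the input's length with no phase lag.
    """
    y = np.asarray(series, dtype=float)
    if window > y.size:
        raise ValueError("window exceeds series length")
    good = np.isfinite(y)
    filled = np.where(good, y, 0.0)
    kernel = np.ones(window)
    left = window // 2  # samples before the center (ceil side)
    sums = np.convolve(filled, kernel, mode="full")
    counts = np.convolve(good.astype(float), kernel, mode="full")
    # center of kernel over sample i sits at full-convolution index i + left
    idx = np.arange(y.size) + window - 1 - left
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums[idx] / counts[idx]
    return out


def butterworth(series, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    Gaps (NaNs) are linearly interpolated before filtering so the recursive
    filter sees a contiguous signal; a single pass would phase-lag the
    series, biasing any curve compared against ground truth, hence
    ``filtfilt``.
    """
    y = np.asarray(series, dtype=float)
    if spec.cutoff >= 0.5 * spec.fs:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if y.size <= 3 * spec.order:
        raise ValueError("series too short for the requested order")
    good = np.isfinite(y)
    if not np.all(good):
        if np.count_nonzero(good) < 2:
            raise ValueError("cannot interpolate: fewer than 2 finite values")
        idx = np.arange(y.size)
        y = np.interp(idx, idx[good], y[good])
    b, a = signal.butter(spec.order, spec.cutoff, btype="low", fs=spec.fs)
    return signal.filtfilt(b, a, y)


def apply_filter(series, spec: FilterSpec) -> np.ndarray:
    """Dispatch on :class:`FilterSpec.kind`."""
    if spec.kind == "moving_average":
        return moving_average(series, spec.window)
    if spec.kind == "butterworth":
        return butterworth(series, spec)
    raise ValueError(f"unknown filter kind {spec.kind!r}")


def _dedupe_mean(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort by x and pool abscissae closer than 1e-5 of the span.

    Pooled sites carry the ordinate mean and a weight equal to the count —
    the identical least-squares objective, but with a guaranteed minimum
    knot gap.  Nearly colliding sites (an angle path revisiting the same
    value to within ~1e-6 of the span) otherwise make the penalized spline
    system numerically singular and the fit collapses.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    tol = np.ptp(xs) * 1e-5
    if tol <= 0:
        raise ValueError("all abscissae identical")
    # group consecutive sorted sites whose gap is below tol
    group = np.concatenate([[0], np.cumsum(np.diff(xs) > tol)])
    cnts = np.bincount(group)
    xu = np.bincount(group, weights=xs) / cnts
    yu = np.bincount(group, weights=ys) / cnts
    return xu, yu, cnts.astype(float)


def smoothing_spline(x, y, p: float) -> Callable[[np.ndarray], np.ndarray]:
    """Cubic smoothing spline minimizing
    ``p * sum (y - s(x))^2 + (1 - p) * int (s'')^2 dx`` (csaps convention).

    Duplicate abscissae are averaged first.  ``p = 1`` returns the
    interpolating natural cubic spline, ``p = 0`` the least-squares
    straight line.  The returned callable evaluates at arbitrary points in
    range.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    xu, yu, wu = _dedupe_mean(x[keep], y[keep])
    if xu.size < 4:
        raise ValueError("need at least 4 distinct abscissae")
    if p == 0.0:
        coef = np.polynomial.polynomial.polyfit(xu, yu, 1, w=np.sqrt(wu))

        def line(xq):
            return np.polynomial.polynomial.polyval(np.asarray(xq, float), coef)

        return line
    if p == 1.0:
        return CubicSpline(xu, yu, bc_type="natural")
    lam = (1.0 - p) / p
    return make_smoothing_spline(xu, yu, w=wu, lam=lam)


def spline_margin_outliers(
    x, y, p: float, margin: float = 0.01
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Spline-based outlier rejection: fit on all points, flag residuals
    beyond ``±margin``, refit on the retained points.

    Returns ``(mask, spline)`` with ``mask`` True at flagged points and the
    refit spline.  Non-finite samples are always flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s0 = smoothing_spline(x, y, p)
    finite = np.isfinite(x) & np.isfinite(y)
    resid = np.full(y.shape, np.inf)
    resid[finite] = np.abs(y[finite] - s0(x[finite]))
    mask = resid > margin
    if np.count_nonzero(~mask) < 4:
        raise ValueError("margin rejected too many points to refit")
    s1 = smoothing_spline(x[~mask], y[~mask], p)
    return mask, s1
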