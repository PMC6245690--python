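"""Gait curves: pendulum-like movement, smoothing and curve comparison.

The pendulum-like movement (PLM) of the hind limb is the angle swept by
the line from the first landmark (5th lumbar vertebra) to the last (5th
metatarsophalangeal joint) over a step.  Here it is measured from the
downward vertical, positive toward +x, so a limb hanging straight down
reads 0 and a forward-swung limb reads positive — the usual pendulum
convention.

Per-frame fits arrive as angle time series with gaps (frames where the
optimizer did not converge).  The analysis pipeline interpolates
interior gaps with a natural cubic spline, averages repeated runs with
objective-value weights, smooths with a median-anchored outlier-
rejecting moving average, and compares curves with the discrete
Fréchet distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist

from .kinematics import LimbModel, joint_points

__all__ = [
    "AngleSeries",
    "plm_angle",
    "flag_low_fitness",
    "interpolate_missing",
    "run_weighted_mean",
    "robust_moving_average",
    "discrete_frechet",
    "normalized_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class AngleSeries:
    """A per-frame angle time series with gaps and per-frame weights.

    ``values`` holds radians with NaN at missing frames; ``weights``
    are per-frame quality weights (typically objective values);
    ``valid`` flags frames that carry a measured or interpolated value.
    """

    frames: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float).copy()
        n = self.frames.size
        if self.values.shape != (n,):
            raise ValueError("frames and values must have equal length")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise ValueError("weights must match the series length")
        finite = np.isfinite(self.values)
        if self.valid is None:
            self.valid = finite
        self.valid = np.asarray(self.valid, dtype=bool) & finite
        self.values[~self.valid] = np.nan

    def copy(self) -> "AngleSeries":
        return AngleSeries(self.frames.copy(), self.values.copy(),
                           self.weights.copy(), self.valid.copy())


def plm_angle(model: LimbModel) -> float:
    """Pendulum-like-movement angle of a fitted model, radians.

    Angle of the P1 -> P5 vector measured from the downward vertical
    (+y in image coordinates), positive toward +x; range (-pi, pi].
    """
    pts = joint_points(model)
    dx, dy = pts[4] - pts[0]
    if math.hypot(dx, dy) < 1e-9:
        raise ValueError("PLM angle undefined: first and last joints coincide")
    return math.atan2(dx, dy)


def flag_low_fitness(fitness, k: float = 3.0) -> np.ndarray:
    """Flag frames whose objective value falls below the sequence's band.

    On a gait sequence the attainable objective varies little from
    frame to frame, so a fit that landed in a wrong local optimum
    shows up as a low outlier.  A frame is flagged when its fitness
    lies more than ``k`` robust sigmas (1.4826 x MAD) below the median
    fitness of the sequence.  Flagged frames are treated as
    non-convergent: their angles are dropped and later filled by
    interpolation.

    Returns a boolean array, True = keep.
    """
    fitness = np.asarray(fitness, dtype=float)
    med = np.median(fitness)
    sigma = 1.4826 * np.median(np.abs(fitness - med))
    if sigma == 0:
        return np.ones_like(fitness, dtype=bool)
    return fitness >= med - k * sigma


def interpolate_missing(series: AngleSeries) -> AngleSeries:
    """Fill interior gaps with a natural cubic spline over frame index.

    Leading/trailing gaps are left missing (no extrapolation).  Filled
    frames get the mean weight of the measured frames.  Requires at
    least 4 measured values.
    """
    out = series.copy()
    valid = out.valid
    if valid.sum() < 4:
        raise ValueError("cubic-spline interpolation needs at least 4 valid points")
    if valid.all():
        return out
    spline = CubicSpline(out.frames[valid], out.values[valid], bc_type="natural")
    first, last = np.flatnonzero(valid)[[0, -1]]
    interior = ~valid
    interior[:first] = False
    interior[last + 1 :] = False
    out.values[interior] = spline(out.frames[interior])
    out.weights[interior] = out.weights[valid].mean()
    out.valid = valid | interior
    return out


def run_weighted_mean(series_list: list[AngleSeries], fitness) -> AngleSeries:
    """Average repeated runs, weighting each by its objective value.

    ``fitness`` is one scalar per run or a (runs, frames) array.  Per
    frame, the weights of the runs that have a valid value there are
    normalized to sum to one; frames where no run is valid stay
    missing.  If all weights at a frame are zero the mean falls back to
    unweighted (logged).
    """
    if len(series_list) == 0:
        raise ValueError("need at least one series")
    frames = series_list[0].frames
    for s in series_list[1:]:
        if not np.array_equal(s.frames, frames):
            raise ValueError("series are not frame-aligned")
    vals = np.vstack([s.values for s in series_list])
    valid = np.vstack([s.valid for s in series_list])
    fit = np.asarray(fitness, dtype=float)
    if fit.ndim == 1:
        fit = np.broadcast_to(fit[:, None], vals.shape).copy()
    if fit.shape != vals.shape:
        raise ValueError("fitness must be per-run scalars or a (runs, frames) array")

    w = np.where(valid, fit, 0.0)
    wsum = w.sum(axis=0)
    any_valid = valid.any(axis=0)
    degenerate = any_valid & (wsum <= 0.0)
    if degenerate.any():
        logger.warning("all-zero weights on %d frame(s); using unweighted mean",
                       int(degenerate.sum()))
        w[:, degenerate] = valid[:, degenerate].astype(float)
        wsum = w.sum(axis=0)

    out_vals = np.full(frames.shape, np.nan)
    np.divide((np.nan_to_num(vals) * w).sum(axis=0), wsum,
              out=out_vals, where=any_valid)
    out_weights = np.zeros(frames.shape)
    out_weights[any_valid] = fit.mean(axis=0)[any_valid]
    return AngleSeries(frames, out_vals, out_weights, any_valid)


def robust_moving_average(
    series: AngleSeries, window: int = 7, outlier_k: float = 6.0
) -> AngleSeries:
    """Median-anchored outlier-rejecting weighted moving average.

    Per frame, the window's median and a robust spread estimate
    (1.4826 x the median absolute deviation, the consistent sigma
    estimate under normality) are computed over valid neighbors;
    points deviating from the median by more than ``outlier_k`` such
    sigmas are excluded and the output is the weight-weighted mean of
    the survivors.  The plain window standard deviation would be
    useless here: one large spike inflates it so much that
    ``|v - median| / std <= sqrt(n)`` for every point, so a 6-sigma
    rule would never fire on desk-scale windows.  Windows are
    truncated at the series edges.  If everything in a window is
    rejected the original value is kept (logged).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    out = series.copy()
    half = window // 2
    n = series.frames.size
    for i in range(n):
        if not series.valid[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = series.valid[lo:hi]
        v = series.values[lo:hi][sel]
        w = series.weights[lo:hi][sel]
        med = np.median(v)
        sigma = 1.4826 * np.median(np.abs(v - med))  # robust sigma (scaled MAD)
        keep = np.abs(v - med) <= outlier_k * sigma
        if not keep.any():  # pragma: no cover - unreachable with median anchor
            logger.warning("all points rejected in window at frame %d; keeping original",
                           series.frames[i])
            continue
        wk = w[keep]
        if wk.sum() > 0:
            out.values[i] = float(np.sum(v[keep] * wk) / wk.sum())
        else:
            out.values[i] = float(v[keep].mean())
    return out


def discrete_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete Fréchet distance between two polygonal curves.

    Dynamic program over monotone couplings of the two point sequences
    with the Euclidean ground metric: the minimal, over couplings, of
    the maximal coupled point-pair distance.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("curves must be non-empty")
    d = cdist(a, b)
    n, m = d.shape
    ca = np.empty_like(d)
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def normalized_curve(series: AngleSeries) -> np.ndarray:
    """(t, value) curve with time normalized to [0, 1], values in radians.

    Only valid frames are included.  Used before Fréchet comparison so
    distances between resampled curves are unitless and comparable.
    """
    valid = series.valid
    if valid.sum() == 0:
        raise ValueError("series has no valid points")
    t = series.frames[valid].astype(float)
    span = t[-1] - t[0]
    t = (t - t[0]) / span if span > 0 else np.zeros_like(t)
    return np.column_stack((t, series.values[valid]))
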