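"""Deterministic two-stage angle/width refinement for one limb.

Given a start point and the four segment lengths, this module finds the
segment angles and widths that maximize the accuracy objective, one
segment at a time from proximal to distal.  Per segment:

* **Stage I** scans the angle over its bounds in coarse (default 4
  degree) steps at a fixed initial width and keeps the best angle.
* **Stage II** rescans one coarse step around that angle in fine
  (default 1 degree) steps and, at each fine angle, scans the width
  over the configured range in 1 px steps; the best (angle, width)
  pair wins.

The candidate score is always the full accuracy of the partial model:
the union of the already-fitted proximal segments (the *context*) and
the candidate rectangle, against the marker mask.  Because the context
is fixed within a segment fit, each candidate only needs the pixels it
adds on top of the context, which makes the scan cheap: a candidate's
score is ``(base + gain) / (P + N)`` where *base* is the context's
agreement count and *gain* counts newly covered marker pixels minus
newly covered background pixels.

Everything here is deterministic; ties are broken toward the smallest
angle, then the smallest width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from numba import njit

from .imaging import render_segment

__all__ = [
    "DEG",
    "AngleBounds",
    "LocalSearchConfig",
    "LocalSearchResult",
    "fit_segment",
    "local_search",
]

DEG = math.pi / 180.0


@dataclass(frozen=True)
class AngleBounds:
    """Closed angular interval [lower, upper], radians (lower <= upper)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("angle bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(f"empty angle range: [{self.lower}, {self.upper}]")
        if self.upper - self.lower > 2.0 * math.pi + 1e-9:
            raise ValueError("angle range wider than a full turn")

    def clip(self, lower: float, upper: float) -> "AngleBounds":
        return AngleBounds(max(self.lower, lower), min(self.upper, upper))


@dataclass
class LocalSearchConfig:
    """Knobs of the two-stage scan.

    coarse_step_deg, fine_step_deg
        Angular resolution of stage I and stage II (degrees).
    initial_width
        Width used throughout stage I (pixels); clamped into the width
        range for stage II comparability.
    width_min, width_max
        Inclusive integer width range scanned in stage II (pixels).
    width_init
        ``"previous"``: stage I of segment n uses segment n-1's fitted
        width; ``"w0"``: always use ``initial_width``.
    first_bounds_deg
        Angular bounds for segment 1 (degrees).
    bound_delta_deg
        After fitting segment n at angle theta, segment n+1's bounds
        become theta +/- this value (degrees).
    offimage_penalty
        Count rendered pixel centers outside the image against the
        objective.  Without it, clipping makes any overshoot past the
        border free and distal segment lengths become unidentifiable
        (a flat plateau in the fitness landscape).
    """

    coarse_step_deg: float = 4.0
    fine_step_deg: float = 1.0
    initial_width: float = 10.0
    width_min: int = 3
    width_max: int = 30
    width_init: str = "previous"
    first_bounds_deg: tuple[float, float] = (-180.0, 180.0)
    bound_delta_deg: float = 90.0
    offimage_penalty: bool = True

    def __post_init__(self) -> None:
        if self.coarse_step_deg <= 0 or self.fine_step_deg <= 0:
            raise ValueError("scan steps must be positive")
        if not (0 < self.width_min <= self.width_max):
            raise ValueError("need 0 < width_min <= width_max")
        if self.width_init not in ("previous", "w0"):
            raise ValueError("width_init must be 'previous' or 'w0'")


@dataclass
class LocalSearchResult:
    """Angles/widths of all four segments plus the full-model scores.

    ``score`` is the plain accuracy of the assembled model's rendering
    against the marker mask; ``objective`` additionally subtracts the
    off-image spill penalty and is the quantity the optimizers rank
    by.  The two coincide whenever the model stays inside the frame.
    """

    thetas: np.ndarray
    widths: np.ndarray
    score: float
    objective: float = 0.0
    segment_scores: list[float] = field(default_factory=list)


def _angle_grid(bounds: AngleBounds, step_rad: float) -> np.ndarray:
    n = int(math.floor((bounds.upper - bounds.lower) / step_rad + 1e-9))
    return bounds.lower + step_rad * np.arange(n + 1)


@njit(cache=True)
def _gain_kernel(contrib, ox, oy, ct, st, length, half_width,
                 r0, r1, c0, c1):  # pragma: no cover - numba
    """Gain of one candidate rectangle; pixel-center inclusion test.

    Pixels outside the ``contrib`` image count -1 (off-image spill).
    Arithmetic matches the rasterizer expression for expression so
    scores agree exactly with rendering plus counting.
    """
    h, w = contrib.shape
    gain = 0
    for r in range(r0, r1 + 1):
        dy = r - oy
        for c in range(c0, c1 + 1):
            dx = c - ox
            t = dx * ct + dy * st
            if t < 0.0 or t > length:
                continue
            perp = dy * ct - dx * st
            if perp < 0.0:
                perp = -perp
            if perp > half_width:
                continue
            if r < 0 or r >= h or c < 0 or c >= w:
                gain -= 1
            else:
                gain += contrib[r, c]
    return gain


@njit(cache=True)
def _width_gain_kernel(contrib, ox, oy, ct, st, length, half_widths,
                       r0, r1, c0, c1, acc):  # pragma: no cover - numba
    """Accumulate per-width gains for one angle in one pass.

    ``acc[i]`` receives contributions of pixels whose perpendicular
    distance first fits width i (ascending half_widths); a cumulative
    sum then yields the gain at every width.
    """
    h, w = contrib.shape
    n = half_widths.shape[0]
    hw_max = half_widths[n - 1]
    for r in range(r0, r1 + 1):
        dy = r - oy
        for c in range(c0, c1 + 1):
            dx = c - ox
            t = dx * ct + dy * st
            if t < 0.0 or t > length:
                continue
            perp = dy * ct - dx * st
            if perp < 0.0:
                perp = -perp
            if perp > hw_max:
                continue
            i = 0
            while half_widths[i] < perp:
                i += 1
            if r < 0 or r >= h or c < 0 or c >= w:
                acc[i] -= 1
            else:
                acc[i] += contrib[r, c]


def _candidate_bbox(shape, origin, length, theta, half_width, offimage_penalty):
    h, w_img = shape
    ox, oy = origin
    ct, st = math.cos(theta), math.sin(theta)
    xs = [ox + t * ct + p * (-st) for t in (0.0, length) for p in (-half_width, half_width)]
    ys = [oy + t * st + p * ct for t in (0.0, length) for p in (-half_width, half_width)]
    c0, c1 = int(math.ceil(min(xs))), int(math.floor(max(xs)))
    r0, r1 = int(math.ceil(min(ys))), int(math.floor(max(ys)))
    if not offimage_penalty:
        c0, c1 = max(0, c0), min(w_img - 1, c1)
        r0, r1 = max(0, r0), min(h - 1, r1)
    return ct, st, r0, r1, c0, c1


def _segment_gain_geometry(contrib, origin, length, theta, half_width,
                           offimage_penalty=True):
    """Axial/perpendicular coordinates of candidate-rectangle pixels.

    Returns (perp_distances, contributions) for integer pixel centers
    inside the candidate rectangle at the *widest* half-width.
    ``contrib`` is +1 on uncovered marker pixels, -1 on uncovered
    background, 0 on pixels already covered by the context.  With
    ``offimage_penalty``, pixel centers outside the image also count
    -1: clipping would otherwise make every overshoot past the border
    free, leaving the objective flat (and distal lengths unidentified)
    once a segment leaves the frame.
    """
    h, w_img = contrib.shape
    ox, oy = origin
    ct, st = math.cos(theta), math.sin(theta)
    xs = [ox + t * ct + p * (-st) for t in (0.0, length) for p in (-half_width, half_width)]
    ys = [oy + t * st + p * ct for t in (0.0, length) for p in (-half_width, half_width)]
    c0, c1 = int(math.ceil(min(xs))), int(math.floor(max(xs)))
    r0, r1 = int(math.ceil(min(ys))), int(math.floor(max(ys)))
    if not offimage_penalty:
        c0, c1 = max(0, c0), min(w_img - 1, c1)
        r0, r1 = max(0, r0), min(h - 1, r1)
    if c0 > c1 or r0 > r1:
        return np.empty(0), np.empty(0, dtype=np.int8)
    cols = np.arange(c0, c1 + 1, dtype=float)[None, :] - ox
    rows = np.arange(r0, r1 + 1, dtype=float)[:, None] - oy
    t = cols * ct + rows * st
    perp = np.abs(rows * ct - cols * st)
    inside = (t >= 0.0) & (t <= length) & (perp <= half_width)
    if offimage_penalty and (c0 < 0 or r0 < 0 or c1 >= w_img or r1 >= h):
        box = np.full(inside.shape, np.int8(-1))
        ir0, ir1 = max(0, r0), min(h - 1, r1)
        ic0, ic1 = max(0, c0), min(w_img - 1, c1)
        if ir0 <= ir1 and ic0 <= ic1:
            box[ir0 - r0 : ir1 - r0 + 1, ic0 - c0 : ic1 - c0 + 1] = \
                contrib[ir0 : ir1 + 1, ic0 : ic1 + 1]
        return perp[inside], box[inside]
    return perp[inside], contrib[r0 : r1 + 1, c0 : c1 + 1][inside]


def _candidate_gain(contrib, origin, length, theta, width, offimage_penalty=True) -> int:
    half = width / 2.0
    ct, st, r0, r1, c0, c1 = _candidate_bbox(contrib.shape, origin, length,
                                             theta, half, offimage_penalty)
    if r0 > r1 or c0 > c1:
        return 0
    return int(_gain_kernel(contrib, origin[0], origin[1], ct, st,
                            float(length), half, r0, r1, c0, c1))


def fit_segment(
    S: np.ndarray,
    origin: tuple[float, float],
    length: float,
    bounds: AngleBounds,
    initial_width: float | None = None,
    context: np.ndarray | None = None,
    config: LocalSearchConfig | None = None,
) -> tuple[float, float, float]:
    """Two-stage scan for one segment's angle and width.

    Parameters
    ----------
    S : bool array
        Marker mask.
    origin : (x, y)
        Proximal joint of the segment.
    length : float
        Segment length (pixels, > 0).
    bounds : AngleBounds
        Angular search interval.
    initial_width : float, optional
        Stage-I width; defaults to the config's ``initial_width``.
    context : bool array, optional
        Rendering of the already-fitted proximal segments.
    config : LocalSearchConfig, optional

    Returns
    -------
    (theta, width, score)
        Best angle (radians), best width (pixels) and the accuracy of
        context + this segment against S.
    """
    cfg = config or LocalSearchConfig()
    if not length > 0:
        raise ValueError(f"segment length must be positive, got {length}")
    S = np.asarray(S, dtype=bool)
    if context is None:
        context = np.zeros_like(S)
    contrib = np.where(S, np.int8(1), np.int8(-1))
    contrib[context] = 0
    base = int(np.count_nonzero(context == S))
    total = S.size
    theta, width, gain = _fit_segment_fast(
        S, contrib, (float(origin[0]), float(origin[1])), float(length), bounds,
        float(initial_width if initial_width is not None else cfg.initial_width), cfg,
    )
    return theta, width, (base + gain) / total


def _fit_segment_fast(S, contrib, origin, length, bounds, initial_width, cfg):
    """Core scan; returns (theta, width, gain) relative to the context."""
    coarse = cfg.coarse_step_deg * DEG
    fine = cfg.fine_step_deg * DEG
    w0 = min(max(initial_width, cfg.width_min), cfg.width_max)

    # Stage I: coarse angle scan at fixed width.
    grid = _angle_grid(bounds, coarse)
    best_theta_I = grid[0]
    best_gain_I = None
    for th in grid:
        g = _candidate_gain(contrib, origin, length, th, w0, cfg.offimage_penalty)
        if best_gain_I is None or g > best_gain_I:
            best_gain_I, best_theta_I = g, th

    # Stage II: fine angle scan around the stage-I winner, full width scan.
    fine_bounds = AngleBounds(
        max(bounds.lower, best_theta_I - coarse),
        min(bounds.upper, best_theta_I + coarse),
    )
    widths = np.arange(cfg.width_min, cfg.width_max + 1, dtype=float)
    half_widths = widths / 2.0
    best = None  # (gain, theta, width)
    acc = np.empty(widths.size, dtype=np.int64)
    for th in _angle_grid(fine_bounds, fine):
        ct, st, r0, r1, c0, c1 = _candidate_bbox(
            contrib.shape, origin, length, th, half_widths[-1], cfg.offimage_penalty)
        if r0 > r1 or c0 > c1:
            gains = np.zeros(widths.size, dtype=np.int64)
        else:
            acc[:] = 0
            _width_gain_kernel(contrib, origin[0], origin[1], ct, st, float(length),
                               half_widths, r0, r1, c0, c1, acc)
            gains = np.cumsum(acc)
        j = int(np.argmax(gains))  # first max -> smallest width
        if best is None or gains[j] > best[0]:
            best = (int(gains[j]), float(th), float(widths[j]))
    gain, theta, width = best
    return theta, width, gain


def local_search(
    S: np.ndarray,
    origin: tuple[float, float],
    lengths,
    bounds: list[AngleBounds] | None = None,
    config: LocalSearchConfig | None = None,
) -> LocalSearchResult:
    """Fit all four segments, proximal to distal.

    After fitting segment ``i`` the next origin is its distal joint and
    segment ``i+1``'s angular bounds become the fitted angle +/- the
    configured delta (unless explicit per-segment ``bounds`` are
    given).  The context mask accumulates each fitted segment.
    """
    cfg = config or LocalSearchConfig()
    S = np.asarray(S, dtype=bool)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (4,):
        raise ValueError(f"need exactly 4 lengths, got shape {lengths.shape}")
    if not np.all(lengths > 0):
        raise ValueError("segment lengths must be strictly positive")

    context = np.zeros_like(S)
    total = S.size
    pos = (float(origin[0]), float(origin[1]))
    thetas = np.empty(4)
    widths = np.empty(4)
    seg_scores: list[float] = []
    prev_width = cfg.initial_width
    delta = cfg.bound_delta_deg * DEG
    obj_correct = int(np.count_nonzero(~S))  # empty context: TN only

    for i in range(4):
        if bounds is not None and bounds[i] is not None:
            b = bounds[i]
        elif i == 0:
            b = AngleBounds(cfg.first_bounds_deg[0] * DEG, cfg.first_bounds_deg[1] * DEG)
        else:
            b = AngleBounds(thetas[i - 1] - delta, thetas[i - 1] + delta)
        init_w = prev_width if cfg.width_init == "previous" else cfg.initial_width
        contrib = np.where(S, np.int8(1), np.int8(-1))
        contrib[context] = 0
        th, w, gain = _fit_segment_fast(S, contrib, pos, float(lengths[i]), b, init_w, cfg)
        obj_correct += gain
        render_segment(context, pos, float(lengths[i]), th, w)
        score = np.count_nonzero(context == S) / total
        thetas[i], widths[i] = th, w
        seg_scores.append(float(score))
        prev_width = w
        pos = (pos[0] + lengths[i] * math.cos(th), pos[1] + lengths[i] * math.sin(th))

    return LocalSearchResult(thetas=thetas, widths=widths, score=seg_scores[-1],
                             objective=obj_correct / total, segment_scores=seg_scores)
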