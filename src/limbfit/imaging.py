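"""Marker segmentation, model rasterization and the accuracy objective.

Binary masks are plain 2D boolean numpy arrays indexed ``[row, col]``,
with ``True`` marking marker (white) pixels.  The fitting objective is
binary-classification accuracy between the rendered model image ``E``
and the segmented marker image ``S``::

    f = (TP + TN) / (P + N)

where TP counts white pixels of E that are white in S, TN counts black
pixels of E that are black in S, and P + N is the total pixel count of
S.  Its maximum value is 1, attained when E equals S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import LimbModel, joint_points, validate

__all__ = [
    "SegmentationParams",
    "segment_frame",
    "render",
    "render_segment",
    "fitting_score",
    "uppermost_candidates",
    "roi_crop",
    "load_mask",
    "save_mask",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Hue-window thresholds for isolating a colored marker.

    Hue is on the [0, 1) circle (multiply by 360 for degrees).  A
    wrap-around window with ``hue_low > hue_high`` selects hues around
    red (e.g. 0.95..0.05).  ``sat_min`` and ``val_min`` are optional
    floors that reject gray/dark pixels whose hue is meaningless.
    """

    hue_low: float
    hue_high: float
    sat_min: float = 0.0
    val_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("hue_low", "hue_high"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        for name in ("sat_min", "val_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def segment_frame(rgb_frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment marker pixels from an RGB frame by HSV hue thresholding.

    A pixel is marked iff its hue falls in the (possibly wrap-around)
    window and its saturation/value clear the configured floors.
    """
    from skimage.color import rgb2hsv

    frame = np.asarray(rgb_frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an RGB frame of shape (H, W, 3), got {frame.shape}")
    hsv = rgb2hsv(frame)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if params.hue_low <= params.hue_high:
        in_window = (hue >= params.hue_low) & (hue <= params.hue_high)
    else:  # wrap-around (red)
        in_window = (hue >= params.hue_low) | (hue <= params.hue_high)
    return in_window & (sat >= params.sat_min) & (val >= params.val_min)


def render_segment(
    out: np.ndarray,
    origin: tuple[float, float],
    length: float,
    theta: float,
    width: float,
) -> None:
    """Rasterize one segment into ``out`` (in place, logical OR).

    The segment is a filled oriented rectangle with square caps: axis
    from ``origin`` along direction ``theta`` for ``length`` pixels,
    thickness ``width``.  A pixel is set iff its center lies inside the
    rectangle (axial coordinate in [0, length], perpendicular distance
    at most width/2); pixels outside the image are clipped.
    """
    if not (length > 0 and width > 0):
        raise ValueError(f"degenerate segment: length={length}, width={width}")
    h, w_img = out.shape
    ox, oy = float(origin[0]), float(origin[1])
    ct, st = math.cos(theta), math.sin(theta)
    # Bounding box of the rectangle's four corners.
    half = width / 2.0
    xs = [ox + t * ct + p * (-st) for t in (0.0, length) for p in (-half, half)]
    ys = [oy + t * st + p * ct for t in (0.0, length) for p in (-half, half)]
    c0 = max(0, int(math.ceil(min(xs))))
    c1 = min(w_img - 1, int(math.floor(max(xs))))
    r0 = max(0, int(math.ceil(min(ys))))
    r1 = min(h - 1, int(math.floor(max(ys))))
    if c0 > c1 or r0 > r1:
        return
    cols = np.arange(c0, c1 + 1, dtype=float)[None, :] - ox
    rows = np.arange(r0, r1 + 1, dtype=float)[:, None] - oy
    t = cols * ct + rows * st
    perp = rows * ct - cols * st
    inside = (t >= 0.0) & (t <= length) & (np.abs(perp) <= half)
    out[r0 : r1 + 1, c0 : c1 + 1] |= inside


def render(model: LimbModel, width: int, height: int) -> np.ndarray:
    """Rasterize all four segments of a model into a binary mask.

    The result is the union of the four per-segment rectangles; union
    is commutative so segment order does not matter.
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    problems = [v for v in validate(model) if "positive" in v or "finite" in v]
    if problems:
        raise ValueError("; ".join(problems))
    out = np.zeros((height, width), dtype=bool)
    pts = joint_points(model)
    for i in range(4):
        render_segment(out, tuple(pts[i]), float(model.lengths[i]),
                       float(model.thetas[i]), float(model.widths[i]))
    return out


def fitting_score(E: np.ndarray, S: np.ndarray) -> float:
    """Accuracy of the rendered mask E against the reference mask S."""
    E = np.asarray(E, dtype=bool)
    S = np.asarray(S, dtype=bool)
    if E.shape != S.shape:
        raise ValueError(f"mask dimensions differ: {E.shape} vs {S.shape}")
    agree = int(np.count_nonzero(E == S))
    return agree / E.size


def uppermost_candidates(
    S: np.ndarray, top_fraction: float = 0.05, min_component: int = 8
) -> np.ndarray:
    """White pixels in the uppermost band of the marker's vertical extent.

    Candidate start points for the chain: all white pixels whose row
    lies within the top ``top_fraction`` of the white-pixel vertical
    extent (at least 2 rows), sorted by (row, column).

    Connected components smaller than ``min_component`` pixels are
    ignored: segmentation masks carry salt specks, and the uppermost
    pixels of the *marker* — not of an isolated noise pixel — are what
    anchor the chain.  Marker strokes are orders of magnitude larger
    than specks, so a small fixed floor is scale-safe.  If nothing
    survives the floor, the raw mask is used.

    Returns
    -------
    ndarray of shape (k, 2)
        Rows are (row, col) pixel coordinates.
    """
    S = np.asarray(S, dtype=bool)
    if not S.any():
        raise ValueError("mask contains no marker pixels")
    if min_component > 1:
        from skimage.morphology import remove_small_objects

        try:
            cleaned = remove_small_objects(S, max_size=min_component - 1)
        except TypeError:  # scikit-image < 0.26
            cleaned = remove_small_objects(S, min_size=min_component)
        if cleaned.any():
            S = cleaned
    white_rows = np.flatnonzero(S.any(axis=1))
    rmin, rmax = int(white_rows[0]), int(white_rows[-1])
    extent = rmax - rmin + 1
    n_rows = min(extent, max(2, math.ceil(top_fraction * extent)))
    cutoff = rmin + n_rows - 1
    coords = np.argwhere(S[: cutoff + 1])  # argwhere is already (row, col) sorted
    return coords


def roi_crop(S: np.ndarray, margin: int = 40) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop a mask to the bounding box of its white pixels, dilated by ``margin``.

    Returns the sub-image and the (row, col) offset of its top-left
    corner in the original image.  Scores computed on the crop use the
    same accuracy formula on fewer pixels; the crop is a speed device
    and changes no geometry (coordinates translate by the offset).
    """
    S = np.asarray(S, dtype=bool)
    if not S.any():
        raise ValueError("mask contains no marker pixels")
    rows = np.flatnonzero(S.any(axis=1))
    cols = np.flatnonzero(S.any(axis=0))
    r0 = max(0, int(rows[0]) - margin)
    r1 = min(S.shape[0] - 1, int(rows[-1]) + margin)
    c0 = max(0, int(cols[0]) - margin)
    c1 = min(S.shape[1] - 1, int(cols[-1]) + margin)
    return S[r0 : r1 + 1, c0 : c1 + 1].copy(), (r0, c0)


def load_mask(path) -> np.ndarray:
    """Read a binary mask from an 8-bit PNG/TIFF (nonzero = white)."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return np.asarray(img) > 0


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
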