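"""Planar kinematic chain of the rat hind limb.

The hind limb is modeled as an open chain of four rigid segments joining
five anatomical landmarks (5th lumbar vertebra, hip, knee, ankle, 5th
metatarsophalangeal joint).  The state is fourteen numbers: the start
point ``(x1, y1)``, four segment lengths ``l1..l4``, four absolute
segment angles ``theta1..theta4`` and four segment widths ``w1..w4``.
Widths carry no kinematic meaning; they exist so the model can be
rasterized and compared against marker images.

Conventions
-----------
Image coordinates: origin at the top-left pixel, ``x`` grows rightward
(columns), ``y`` grows downward (rows), 0-based, sub-pixel positions
allowed.  Angles are in radians measured from the +x axis toward +y
(clockwise on screen).  Each angle is *absolute*, i.e. measured from the
global x axis, not relative to the previous segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "LimbModel",
    "joint_points",
    "encode",
    "decode",
    "validate",
    "wrap_angle",
]

#: Canonical flat-vector field order.
PARAM_NAMES = (
    "x1", "y1",
    "l1", "l2", "l3", "l4",
    "theta1", "theta2", "theta3", "theta4",
    "w1", "w2", "w3", "w4",
)


@dataclass(frozen=True, eq=False)
class LimbModel:
    """Fourteen-parameter hind-limb state.

    Parameters
    ----------
    x1, y1 : float
        Start point (uppermost landmark), pixels.
    lengths : array-like of 4 floats
        Segment lengths, pixels.
    thetas : array-like of 4 floats
        Absolute segment angles, radians from +x toward +y.
    widths : array-like of 4 floats
        Segment widths used for rasterization, pixels.
    """

    x1: float
    y1: float
    lengths: np.ndarray
    thetas: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lengths", "thetas", "widths"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (4,):
                raise ValueError(f"{name} must have exactly 4 entries, got shape {arr.shape}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "x1", float(self.x1))
        object.__setattr__(self, "y1", float(self.y1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LimbModel):
            return NotImplemented
        return bool(np.array_equal(encode(self), encode(other)))

    @property
    def start(self) -> tuple[float, float]:
        return (self.x1, self.y1)


def joint_points(model: LimbModel) -> np.ndarray:
    """Forward kinematics: positions of the five joints.

    Joint ``n`` (1-based) is obtained from joint ``n-1`` by stepping
    ``l_{n-1}`` pixels along direction ``theta_{n-1}``::

        x_n = x_{n-1} + l_{n-1} cos(theta_{n-1})
        y_n = y_{n-1} + l_{n-1} sin(theta_{n-1})

    Returns
    -------
    ndarray of shape (5, 2)
        Rows are joints P1..P5; columns are (x, y) in pixels.
    """
    vec = encode(model)
    if not np.all(np.isfinite(vec)):
        raise ValueError("model contains non-finite parameters")
    steps = model.lengths[:, None] * np.column_stack(
        (np.cos(model.thetas), np.sin(model.thetas))
    )
    pts = np.empty((5, 2), dtype=float)
    pts[0] = (model.x1, model.y1)
    pts[1:] = pts[0] + np.cumsum(steps, axis=0)
    return pts


def encode(model: LimbModel) -> np.ndarray:
    """Flatten a model into the canonical 14-vector.

    Order: ``[x1, y1, l1, l2, l3, l4, theta1..theta4, w1..w4]``.
    """
    return np.concatenate(
        ([model.x1, model.y1], model.lengths, model.thetas, model.widths)
    )


def decode(vector: np.ndarray) -> LimbModel:
    """Inverse of :func:`encode`.

    The constructor is lenient (it checks only shape); semantic problems
    such as non-positive lengths are reported by :func:`validate`.
    """
    vec = np.asarray(vector, dtype=float).ravel()
    if vec.shape != (14,):
        raise ValueError(f"expected a 14-entry parameter vector, got shape {vec.shape}")
    return LimbModel(
        x1=vec[0], y1=vec[1],
        lengths=vec[2:6], thetas=vec[6:10], widths=vec[10:14],
    )


def validate(
    model: LimbModel,
    image_width: int | None = None,
    image_height: int | None = None,
    margin: float = 50.0,
) -> list[str]:
    """Check model invariants; return a list of violation messages.

    An empty list means the model is valid.  When image dimensions are
    given, joints lying more than ``margin`` pixels outside the image
    are also flagged.
    """
    violations: list[str] = []
    vec = encode(model)
    for name, value in zip(PARAM_NAMES, vec):
        if not math.isfinite(value):
            violations.append(f"{name} is not finite ({value!r})")
    for i in range(4):
        if not (model.lengths[i] > 0):
            violations.append(f"l{i + 1} must be strictly positive, got {model.lengths[i]}")
        if not (model.widths[i] > 0):
            violations.append(f"w{i + 1} must be strictly positive, got {model.widths[i]}")
    if violations:
        return violations
    if image_width is not None and image_height is not None:
        pts = joint_points(model)
        for n, (x, y) in enumerate(pts, start=1):
            if (
                x < -margin
                or x > image_width - 1 + margin
                or y < -margin
                or y > image_height - 1 + margin
            ):
                violations.append(
                    f"joint P{n} at ({x:.1f}, {y:.1f}) lies more than {margin:g} px "
                    f"outside the {image_width}x{image_height} image"
                )
    return violations


def wrap_angle(theta):
    """Normalize angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped
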