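"""Synthetic gait sequences with known ground truth.

Generates hind-limb models following smooth periodic joint-angle
trajectories, renders them to binary masks, and optionally degrades
the masks with salt-and-pepper noise and rectangular occlusions.  The
defaults emulate the recording conditions of typical rodent gait
videos: 640x480 frames at 90 fps, one step cycle of about half a
second, segment lengths and widths in the ranges observed on real
animals.  Every generated frame carries its true 14-parameter vector
and true PLM angle, so parameter recovery can be measured exactly.

Joint-angle trajectories are sinusoids (mean + amplitude * sin); a
real step cycle is periodic and smooth but not sinusoidal, so these
sequences exercise the fitting and smoothing machinery without
claiming biological realism.  The default trajectory means keep the
zigzag posture of the limb (alternating segment directions with
consecutive-segment angles of roughly 45-85 degrees) throughout the
cycle, mirroring the permanent hip/knee/ankle flexion of the rat hind
limb; a near-collinear chain would be both unanatomical and poorly
identified from its silhouette, since sliding segment boundaries
along a straight stroke barely changes the image.  Segment lengths
carry a small periodic jitter emulating the apparent-length changes
caused by out-of-plane limb motion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_analysis import plm_angle
from .imaging import render, save_mask
from .kinematics import PARAM_NAMES, LimbModel, encode, validate

__all__ = ["GaitParams", "gait_trajectory", "render_sequence", "write_dataset"]

DEG = math.pi / 180.0


@dataclass
class GaitParams:
    """Ground-truth gait generator parameters (pixels, radians, frames).

    Per joint i, the angle trajectory is
    ``mean_i + amplitude_i * sin(2 pi frame / frames_per_cycle + phase_i)``
    and the nominal length is modulated by a sinusoid of relative
    amplitude ``length_jitter``.  The start point drifts horizontally
    by ``drift_per_cycle`` pixels per cycle (walking).  ``noise_rate``
    flips each mask pixel independently; ``n_occlusions`` rectangles of
    ``occlusion_size`` are blacked out at random positions per frame.
    """

    image_width: int = 640
    image_height: int = 480
    n_frames: int = 45
    frames_per_cycle: int = 45
    start_x: float = 256.0
    start_y: float = 72.0
    drift_per_cycle: float = 40.0
    lengths: tuple = (67.2, 108.1, 94.4, 101.6)
    widths: tuple = (15.7, 15.6, 15.4, 14.6)
    theta_mean_deg: tuple = (115.0, 62.0, 120.0, 45.0)
    theta_amp_deg: tuple = (8.0, 12.0, 12.0, 15.0)
    theta_phase: tuple = (0.0, 0.6, 1.2, 1.8)
    length_jitter: float = 0.03
    noise_rate: float = 0.0
    n_occlusions: int = 0
    occlusion_size: tuple = (40, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.n_frames < 1 or self.frames_per_cycle < 1:
            raise ValueError("frame counts must be positive")

    @classmethod
    def scaled(cls, factor: float, **overrides) -> "GaitParams":
        """Geometry scaled uniformly by ``factor`` (e.g. 0.25 -> 160x120)."""
        p = cls(
            image_width=round(640 * factor),
            image_height=round(480 * factor),
            start_x=256.0 * factor,
            start_y=72.0 * factor,
            drift_per_cycle=40.0 * factor,
            lengths=tuple(l * factor for l in cls.lengths),
            widths=tuple(max(3.0, w * factor) for w in cls.widths),
        )
        return dataclasses.replace(p, **overrides)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GaitParams":
        data = json.loads(text)
        for k in ("lengths", "widths", "theta_mean_deg", "theta_amp_deg",
                  "theta_phase", "occlusion_size"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


def gait_trajectory(params: GaitParams) -> list[LimbModel]:
    """Ground-truth models for each frame of a synthetic gait sequence.

    Deterministic given the parameters.  Raises if any joint leaves the
    image at any frame.
    """
    models: list[LimbModel] = []
    means = np.asarray(params.theta_mean_deg) * DEG
    amps = np.asarray(params.theta_amp_deg) * DEG
    phases = np.asarray(params.theta_phase)
    nominal = np.asarray(params.lengths, dtype=float)
    for k in range(params.n_frames):
        phi = 2.0 * math.pi * k / params.frames_per_cycle
        thetas = means + amps * np.sin(phi + phases)
        lengths = nominal * (1.0 + params.length_jitter * np.sin(phi + phases + 0.5))
        x1 = params.start_x + params.drift_per_cycle * k / params.frames_per_cycle
        model = LimbModel(x1=x1, y1=params.start_y, lengths=lengths,
                          thetas=thetas, widths=np.asarray(params.widths, float))
        problems = validate(model, params.image_width, params.image_height, margin=0.0)
        if problems:
            raise ValueError(f"frame {k}: {'; '.join(problems)}")
        models.append(model)
    return models


def render_sequence(
    models: list[LimbModel],
    params: GaitParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render each model and apply the configured degradations.

    Returns the list of masks and a truth table with one row per frame:
    the 14 true parameters (canonical order) plus the true PLM angle.
    """
    if rng is None:
        rng = params.seed
    rng = np.random.default_rng(rng)
    masks: list[np.ndarray] = []
    rows = []
    for k, model in enumerate(models):
        mask = render(model, params.image_width, params.image_height)
        if params.noise_rate > 0:
            flips = rng.random(mask.shape) < params.noise_rate
            mask = mask ^ flips
        for _ in range(params.n_occlusions):
            oh, ow = params.occlusion_size
            r = int(rng.integers(0, max(1, params.image_height - oh + 1)))
            c = int(rng.integers(0, max(1, params.image_width - ow + 1)))
            mask[r : r + oh, c : c + ow] = False
        masks.append(mask)
        rows.append([k, *encode(model), plm_angle(model)])
    truth = pd.DataFrame(rows, columns=["frame", *PARAM_NAMES, "plm"])
    return masks, truth


def write_dataset(out_dir, masks, truth: pd.DataFrame, params: GaitParams) -> None:
    """Write ``frame_%04d.png``, ``truth.csv`` and ``params.json``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, mask in enumerate(masks):
        save_mask(out / f"frame_{k:04d}.png", mask)
    truth.to_csv(out / "truth.csv", index=False)
    (out / "params.json").write_text(params.to_json())
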