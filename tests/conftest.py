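import numpy as np
import pytest

from limbfit import GaitParams, LimbModel, gait_trajectory, render_sequence


def random_model(rng: np.random.Generator, width: int = 160, height: int = 120) -> LimbModel:
    """A random, mostly in-image limb model for property tests."""
    return LimbModel(
        x1=rng.uniform(0.3 * width, 0.7 * width),
        y1=rng.uniform(0.05 * height, 0.2 * height),
        lengths=rng.uniform(10, 0.2 * height, size=4),
        thetas=rng.uniform(0.2, np.pi - 0.2, size=4),
        widths=rng.uniform(3, 8, size=4),
    )


@pytest.fixture(scope="session")
def quarter_scale_frame():
    """One noiseless 160x120 synthetic frame with its ground-truth model."""
    params = GaitParams.scaled(0.25, n_frames=1, frames_per_cycle=30,
                               length_jitter=0.0, seed=1)
    models = gait_trajectory(params)
    masks, truth = render_sequence(models, params)
    return masks[0], models[0], params
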