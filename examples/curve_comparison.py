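"""Compare two gait curves with the discrete Fréchet distance.

Builds two synthetic PLM curves — the same step observed with different
phase lag and amplitude, mimicking two annotators of the same sequence —
normalizes time to [0, 1] and prints their discrete Fréchet distance.
The distance is the length of the shortest 'dog leash' that lets two
walkers traverse both curves monotonically; 0 means identical curves,
and larger values quantify shape + timing disagreement.
"""

import numpy as np

from limbfit import AngleSeries, discrete_frechet, normalized_curve

frames = np.arange(30)
truth = 0.35 * np.sin(2 * np.pi * frames / 30)
observer = 0.32 * np.sin(2 * np.pi * (frames - 1.5) / 30) + 0.02

a = normalized_curve(AngleSeries(frames, truth))
b = normalized_curve(AngleSeries(frames, observer))

print(f"identical curves:      {discrete_frechet(a, a):.4f}")
print(f"truth vs observer:     {discrete_frechet(a, b):.4f}")
shifted = a.copy()
shifted[:, 1] += 0.25
print(f"vertical +0.25 shift:  {discrete_frechet(a, shifted):.4f} (equals the shift)")
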