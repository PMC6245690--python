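# Methods

## Model

The rat hind limb is modeled as an open planar chain of four rigid
segments joining five landmarks: 5th lumbar vertebra (P1), hip, knee,
ankle and 5th metatarsophalangeal joint (P5). The state is the
14-vector `[x1, y1, l1..l4, θ1..θ4, w1..w4]`. Coordinates are image
coordinates (origin top-left, x rightward, y downward, 0-based,
sub-pixel); angles are absolute — each measured from the global +x
axis toward +y — so forward kinematics is the plain cumulative sum
`P_{n+1} = P_n + l_n (cos θ_n, sin θ_n)`. Angles are stored unwrapped
during optimization (no modulo discontinuities) and normalized to
(−π, π] in outputs. Widths `w_i` carry no kinematic meaning; they
exist so the chain can be rasterized and compared with marker images.

## Rasterization

Each segment is a filled oriented rectangle with square caps: a pixel
is set iff its center lies at axial coordinate within [0, l] and
perpendicular distance at most w/2 from the segment axis. No
anti-aliasing; the union of the four rectangles is the model image.
This rule is deterministic and directly checkable against a per-pixel
enumeration oracle, which the tests do.

## Objective

The fitting score is binary-classification accuracy between the
rendered model image E and the segmented marker mask S:
`f = (TP + TN)/(P + N)`, maximum 1 at E = S. Two deliberate additions:

* **Off-image penalty (optimizers only).** Rendered pixel centers
  falling outside the frame count −1 toward the *selection* objective.
  Pure clipping would make any overshoot past the border free, leaving
  distal segment lengths on a flat fitness plateau (observed as
  unbounded growth of l4 whenever the chain tip nears the border). The
  *reported* fitness of a result remains the plain accuracy; the two
  coincide for models that stay inside the frame, which all correct
  fits do.
* **Region-of-interest crop (optional).** `roi_crop` trims a mask to
  the marker bounding box dilated by a margin (default 40 px). It is a
  speed device only: the same formula on fewer pixels, with
  coordinates translated back afterwards.

## Segmentation

RGB frames are converted to HSV and thresholded on hue, with optional
saturation/value floors that reject gray or dark pixels whose hue is
meaningless. Hue is on [0, 1); a wrap-around window (low > high)
selects red markers. The CLI accepts degrees and converts.

## Local search (angles and widths)

Given the start point and the four lengths, segments are fitted
proximal to distal. Per segment: stage I scans the angle over its
bounds in 4° steps at a fixed probe width and keeps the best angle;
stage II rescans ±4° around it in 1° steps and, at each angle, scans
integer widths over the configured range, keeping the best (angle,
width) pair. The candidate score is always the objective of the
partial model (already-fitted segments plus the candidate), so
segments stay coupled. After segment i, the next origin is its distal
joint and segment i+1's bounds become θ_i ± 90° (configurable);
segment 1 defaults to the full circle. Stage I's probe width defaults
to the previous segment's fitted width (w0 = 10 px for segment 1 at
full 640×480 scale). Everything is deterministic; ties break toward
the smallest angle, then the smallest width. On noiseless
single-segment instances the result equals the exhaustive 1° × 1 px
grid argmax (tested).

Scan steps (4°, 1°, 1 px) are defaults, not hard-coded. The width
range defaults to 3–30 px at full scale; at reduced resolutions the
probe geometry scales with the scene (the quarter-scale tests use
initial width 3 px and range 2–8 px, matching ~4 px stroke widths).

## Genetic algorithm (start pixel and lengths)

The GA owns the variables the local search does not: the index of a
candidate start pixel and the four lengths. Candidates are the marker
pixels whose row lies in the top 5% of the marker's vertical extent
(min 2 rows), sorted by (row, column); connected components smaller
than 8 pixels are ignored when locating that band, because salt
specks in a segmentation mask would otherwise stretch the "vertical
extent" to the whole frame and anchor the chain on noise.

One generation: copy the top `n_elite` unchanged; fill the rest with
children bred by binary tournament (two draws with replacement, fitter
wins, ties random), SBX crossover applied per parent pair with
probability 0.9 (within a crossing pair every gene crosses with its
own uniform draw; children's gene sums equal the parents'), and
polynomial mutation per gene with probability 0.11 (perturbation
δ·(upper−lower), δ from the polynomial density with index η_m = 20).
The pixel index is treated as continuous during operator arithmetic,
then rounded half-up and clamped; lengths clamp to [l_min, l_max]
(default 10 px to half the image diagonal). Evaluation of a chromosome
runs the local search and scores the completed 14-parameter model; a
cache keyed by the exact genome avoids re-evaluating duplicates (the
local search is deterministic, so this is exact).

Defaults mirror the reported experimental setup: population 400, 3
elites, crossover 0.9, mutation 0.11, SBX index η_c = 1, stop when the
best-ever fitness has not improved for `N_maxelite = 8` consecutive
generations (the run ends on the first generation after 8 stagnant
ones), with a safety cap of 100 generations. η_m is the literature's
conventional 20. Fixed seed ⇒ bit-identical results.

## Gait analysis

* **PLM angle**: direction of the P1→P5 vector measured from the
  downward vertical (+y), positive toward +x — the pendulum
  convention, so a limb hanging straight down reads 0. The reference
  axis is a convention choice; comparisons are internally consistent.
* **Gap filling**: natural cubic spline over frame index for interior
  gaps; no extrapolation at the edges; ≥ 4 measured points required.
* **Run averaging**: per frame, the objective values of the runs that
  produced a value are normalized to sum to one and used as weights;
  all-zero weights fall back to the unweighted mean (logged).
* **Robust smoothing**: per frame, a truncated window (default 7
  frames) is summarized by its median and a robust spread estimate,
  1.4826 × the median absolute deviation; points deviating from the
  median by more than 6 such sigmas are excluded and the survivors are
  averaged with their quality weights. The plain window standard
  deviation cannot serve here: a single large spike inflates it so
  much that |v − median|/std ≤ √n for every point, and a 6σ rule would
  never fire on desk-scale windows. The scaled MAD is the standard
  robust σ estimate and makes the 6σ parameter meaningful.
* **Curve comparison**: discrete Fréchet distance (dynamic program
  over monotone couplings, Euclidean ground metric) between curves
  with time normalized to [0, 1] and values in radians. The discrete
  variant is the natural object for per-frame samples; it matches a
  brute-force coupling enumeration exactly on small curves (tested).

## Synthetic data

The generator emulates the recording conditions of rodent gait videos
(640×480, 90 fps, one step cycle ≈ 0.5 s) with known ground truth.
Joint angles follow sinusoids (mean + amplitude·sin over the cycle);
the default means (115°, 62°, 120°, 45°) and amplitudes (8–15°) keep
the limb's zigzag posture — consecutive segment directions 45–85°
apart throughout the cycle — mirroring the permanent hip/knee/ankle
flexion of the rat hind limb. This matters for identifiability, not
just realism: a near-collinear chain is ill-posed, because sliding a
segment boundary along a straight stroke barely changes the
silhouette. Segment lengths and widths default to the magnitudes
observed on real animals (≈ 67/108/94/102 px and ≈ 15 px at full
scale) with a small periodic length jitter standing in for
out-of-plane motion; the start point drifts horizontally (walking).
Degradations: independent per-pixel flips (salt-and-pepper) at a
configurable rate and random black-out rectangles (occlusion).
`GaitParams.scaled(f)` scales the whole scene uniformly; tests run at
f = 0.25 (160×120).

What the generator does *not* emulate: non-sinusoidal phase structure
of real steps (stance/swing asymmetry), motion blur, non-uniform
marker paint, skin deformation, and perspective. Passing tests
therefore demonstrate correct mechanics and recoverability under
controlled degradation, not performance on real video.

## Test problem sizes

The suite runs fitting tests at quarter scale (160×120, population
40, scaled probe widths) so the whole suite stays desk-scale:
single-frame fits take seconds, the multi-frame pipeline minutes.
Dispersion-across-runs checks use population 400 on one frame — the
reported full-scale population — since run-to-run stability is
exactly what a larger population buys.

## Known limitations

* Per-run full-parameter recovery at the scaled test conditions
  (population 40) succeeds in roughly two-thirds of runs; the failure
  mode is a single "chain-lag" local optimum in which shortened middle
  lengths split one stroke and the distal stroke goes uncovered.
  Escaping it needs a coordinated two-gene jump that a 40-individual
  population rarely produces before the stagnation rule fires. Larger
  populations suppress it; repeated independent executions with
  objective-weighted averaging (the intended analysis protocol) hide
  it almost entirely. Distal parameters (l4, θ4) are intrinsically the
  least stable — consistent with the large distal run-to-run
  variability reported for this family of fitters on real data.
* The accuracy objective is dominated by true negatives on large
  frames; scores cluster near 1 and differences of 10⁻³ matter. The
  implementation therefore works with integer agreement counts
  internally.
* The discrete Fréchet distance is O(nm) with a Python loop; fine for
  gait curves (tens to hundreds of points), not for very long series.
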