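import itertools
import math

import numpy as np
import pytest

from limbfit import (
    AngleSeries,
    LimbModel,
    discrete_frechet,
    interpolate_missing,
    joint_points,
    normalized_curve,
    plm_angle,
    robust_moving_average,
    run_weighted_mean,
)
from tests.conftest import random_model


def brute_force_frechet(a, b):
    """Enumerate every monotone coupling explicitly; min over max pair distance."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)

    def dist(i, j):
        return float(np.linalg.norm(a[i] - b[j]))

    best = [math.inf]

    def walk(i, j, worst):
        worst = max(worst, dist(i, j))
        if worst >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = worst
            return
        if i + 1 < n:
            walk(i + 1, j, worst)
        if j + 1 < m:
            walk(i, j + 1, worst)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, worst)

    walk(0, 0, 0.0)
    return best[0]


class TestPlmAngle:
    def test_straight_down_is_zero(self):
        m = LimbModel(50, 10, [10] * 4, [math.pi / 2] * 4, [3] * 4)
        assert plm_angle(m) == pytest.approx(0.0)

    def test_horizontal_right_is_plus_half_pi(self):
        m = LimbModel(10, 50, [10] * 4, [0.0] * 4, [3] * 4)
        assert plm_angle(m) == pytest.approx(math.pi / 2)

    def test_matches_atan2_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = random_model(rng)
            pts = joint_points(m)
            expected = math.atan2(pts[4, 0] - pts[0, 0], pts[4, 1] - pts[0, 1])
            assert plm_angle(m) == pytest.approx(expected, abs=1e-12)

    def test_coincident_endpoints_raise(self):
        m = LimbModel(0, 0, [10, 10, 10, 10],
                      [0, math.pi / 2, math.pi, 3 * math.pi / 2], [3] * 4)
        with pytest.raises(ValueError):
            plm_angle(m)


class TestInterpolateMissing:
    def test_no_missing_unchanged(self):
        s = AngleSeries(np.arange(6), np.linspace(0, 1, 6))
        out = interpolate_missing(s)
        assert np.allclose(out.values, s.values)

    def test_linear_gap_filled_on_line(self):
        vals = np.arange(8, dtype=float) * 0.3 + 1.0
        vals[3] = np.nan
        out = interpolate_missing(AngleSeries(np.arange(8), vals))
        assert out.values[3] == pytest.approx(3 * 0.3 + 1.0, abs=1e-9)

    def test_sinusoid_gaps_recovered(self):
        frames = np.arange(20)
        truth = 0.5 * np.sin(2 * np.pi * frames / 20)
        vals = truth.copy()
        vals[[6, 13]] = np.nan
        out = interpolate_missing(AngleSeries(frames, vals))
        assert np.abs(out.values[[6, 13]] - truth[[6, 13]]).max() < 0.02

    def test_edges_not_extrapolated(self):
        vals = np.array([np.nan, 1.0, 2.0, np.nan, 4.0, 5.0, np.nan])
        out = interpolate_missing(AngleSeries(np.arange(7), vals))
        assert not out.valid[0] and not out.valid[6]
        assert out.valid[3]

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            interpolate_missing(AngleSeries(np.arange(3), np.ones(3)))


class TestRunWeightedMean:
    def test_single_run_identity(self):
        s = AngleSeries(np.arange(5), np.linspace(-1, 1, 5))
        out = run_weighted_mean([s], np.array([0.7]))
        assert np.allclose(out.values, s.values)

    def test_equal_fitness_is_arithmetic_mean(self):
        f = np.arange(4)
        a = AngleSeries(f, np.array([0.0, 1.0, 2.0, 3.0]))
        b = AngleSeries(f, np.array([1.0, 2.0, 3.0, 4.0]))
        out = run_weighted_mean([a, b], np.array([0.5, 0.5]))
        assert np.allclose(out.values, [0.5, 1.5, 2.5, 3.5])

    def test_hand_computed_weighted_mean(self):
        f = np.arange(1)
        a = AngleSeries(f, np.array([0.0]))
        b = AngleSeries(f, np.array([1.0]))
        out = run_weighted_mean([a, b], np.array([0.75, 0.25]))
        assert out.values[0] == pytest.approx(0.25)

    def test_missing_runs_excluded_per_frame(self):
        f = np.arange(3)
        a = AngleSeries(f, np.array([0.0, np.nan, 2.0]))
        b = AngleSeries(f, np.array([1.0, 1.0, np.nan]))
        out = run_weighted_mean([a, b], np.array([0.5, 0.5]))
        assert out.values[1] == pytest.approx(1.0)
        assert out.values[2] == pytest.approx(2.0)
        assert np.all(out.valid)


class TestRobustMovingAverage:
    def test_constant_series_unchanged(self):
        s = AngleSeries(np.arange(11), np.full(11, 0.4))
        out = robust_moving_average(s)
        assert np.allclose(out.values, 0.4)

    def test_extreme_spike_removed(self):
        vals = np.full(15, 1.0)
        vals[7] = 100.0
        out = robust_moving_average(AngleSeries(np.arange(15), vals), window=7)
        assert out.values[7] == pytest.approx(1.0)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(9)
        reduced = 0
        for _ in range(100):
            vals = rng.normal(size=40)
            out = robust_moving_average(AngleSeries(np.arange(40), vals), window=7)
            if np.var(out.values) < np.var(vals):
                reduced += 1
        assert reduced == 100

    def test_output_within_window_range(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=30)
        s = AngleSeries(np.arange(30), vals)
        out = robust_moving_average(s, window=5)
        for i in range(30):
            lo, hi = max(0, i - 2), min(30, i + 3)
            assert vals[lo:hi].min() - 1e-12 <= out.values[i] <= vals[lo:hi].max() + 1e-12

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            robust_moving_average(AngleSeries(np.arange(5), np.ones(5)), window=4)


class TestDiscreteFrechet:
    def test_identical_curves_zero(self):
        a = np.array([[0, 0], [1, 2], [3, 1]], float)
        assert discrete_frechet(a, a) == 0.0

    def test_single_points_euclidean(self):
        assert discrete_frechet([[0, 0]], [[3, 4]]) == pytest.approx(5.0)

    def test_parallel_lines(self):
        a = [[0, 0], [1, 0], [2, 0]]
        b = [[0, 1], [1, 1], [2, 1]]
        assert discrete_frechet(a, b) == pytest.approx(1.0)

    def test_symmetry_and_hausdorff_lower_bound(self):
        rng = np.random.default_rng(12)
        from scipy.spatial.distance import cdist

        for _ in range(50):
            a = rng.normal(size=(rng.integers(2, 7), 2))
            b = rng.normal(size=(rng.integers(2, 7), 2))
            d = discrete_frechet(a, b)
            assert d == pytest.approx(discrete_frechet(b, a))
            dm = cdist(a, b)
            hausdorff = max(dm.min(axis=1).max(), dm.min(axis=0).max())
            assert d >= hausdorff - 1e-12

    def test_matches_brute_force_coupling_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = rng.normal(size=(rng.integers(1, 7), 2))
            b = rng.normal(size=(rng.integers(1, 7), 2))
            assert discrete_frechet(a, b) == pytest.approx(brute_force_frechet(a, b))

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 2)), np.array([[0, 0]]))


def test_normalized_curve_time_in_unit_interval():
    s = AngleSeries(np.array([3, 5, 9, 11]), np.array([0.1, np.nan, 0.3, 0.2]))
    c = normalized_curve(s)
    assert c.shape == (3, 2)
    assert c[0, 0] == 0.0 and c[-1, 0] == 1.0
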