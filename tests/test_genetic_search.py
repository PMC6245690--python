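import math

import numpy as np
import pytest
from scipy import stats

from limbfit import (
    GAConfig,
    Genome,
    Individual,
    LocalSearchConfig,
    fit_frame,
    init_population,
    mutation_delta,
    polynomial_mutation,
    sbx_crossover,
    sbx_values,
    tournament_select,
    wrap_angle,
)
from limbfit.genetic_search import evaluate
from limbfit.imaging import uppermost_candidates

SMALL_LS = LocalSearchConfig(initial_width=3, width_min=2, width_max=8)


class TestSBX:
    def test_u_half_reproduces_parents(self):
        c1, c2 = sbx_values(3.0, 7.0, 0.5, eta_c=1.0)
        assert c1 == pytest.approx(3.0) and c2 == pytest.approx(7.0)

    def test_hand_computed_example(self):
        # u=0.9, eta_c=1, parents 0 and 1: beta = sqrt(5)
        c1, c2 = sbx_values(0.0, 1.0, 0.9, eta_c=1.0)
        beta = math.sqrt(5)
        assert beta == pytest.approx(2.2360679, abs=1e-6)
        assert c1 == pytest.approx(0.5 * (1 - beta), abs=1e-9)  # ~ -0.6180
        assert c2 == pytest.approx(0.5 * (1 + beta), abs=1e-9)  # ~ +1.6180

    def test_children_sum_preserved(self):
        rng = np.random.default_rng(17)
        for _ in range(10_000):
            p1, p2, u = rng.uniform(-50, 50), rng.uniform(-50, 50), rng.random()
            c1, c2 = sbx_values(p1, p2, u, eta_c=rng.uniform(0.5, 5))
            assert c1 + c2 == pytest.approx(p1 + p2, rel=1e-9, abs=1e-9)

    def test_genome_crossover_respects_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            g1 = Genome(int(rng.integers(0, 30)), tuple(rng.uniform(10, 90, 4)))
            g2 = Genome(int(rng.integers(0, 30)), tuple(rng.uniform(10, 90, 4)))
            c1, c2 = sbx_crossover(g1, g2, 1.0, rng, (10.0, 90.0), 30)
            for c in (c1, c2):
                assert 0 <= c.pixel_index < 30
                assert all(10.0 <= l <= 90.0 for l in c.lengths)


class TestPolynomialMutation:
    def test_u_half_leaves_gene_unchanged(self):
        assert mutation_delta(0.5, 20.0) == pytest.approx(0.0)

    def test_delta_distribution_matches_printed_density(self):
        # KS test of 1e5 inverse-CDF draws against the analytic CDF of
        # P(delta) = 0.5 (eta_m + 1) (1 - |delta|)^eta_m
        eta_m = 20.0
        rng = np.random.default_rng(123)
        draws = np.array([mutation_delta(u, eta_m) for u in rng.random(100_000)])

        def cdf(d):
            d = np.asarray(d, dtype=float)
            neg = 0.5 * (1.0 + d) ** (eta_m + 1.0)
            pos = 1.0 - 0.5 * (1.0 - d) ** (eta_m + 1.0)
            return np.where(d < 0, neg, pos)

        result = stats.kstest(draws, cdf)
        assert result.pvalue > 0.01
        assert np.all((draws > -1) & (draws < 1))

    def test_mutated_genes_within_bounds(self):
        rng = np.random.default_rng(31)
        cfg = GAConfig(population_size=4, mutation_prob=1.0)
        for _ in range(500):
            g = Genome(int(rng.integers(0, 12)), tuple(rng.uniform(10, 60, 4)))
            m = polynomial_mutation(g, cfg, rng, (10.0, 60.0), 12)
            assert 0 <= m.pixel_index < 12
            assert all(10.0 <= l <= 60.0 for l in m.lengths)


class TestTournament:
    def _pop(self, fitnesses):
        return [Individual(Genome(0, (10.0,) * 4), fitness=f) for f in fitnesses]

    def test_better_of_two_always_wins(self):
        rng = np.random.default_rng(1)
        pop = self._pop([0.9, 0.1])
        wins = sum(tournament_select(pop, rng).fitness == 0.9 for _ in range(2000))
        # best wins every pair containing it: P = 3/4 under with-replacement draws
        assert wins / 2000 == pytest.approx(0.75, abs=0.04)

    def test_rank_win_rates_match_enumeration(self):
        # P(rank-k wins a with-replacement pair) = (2(n-k)+1)/n^2
        rng = np.random.default_rng(2)
        n = 5
        fitnesses = [0.9, 0.7, 0.5, 0.3, 0.1]
        pop = self._pop(fitnesses)
        counts = {f: 0 for f in fitnesses}
        draws = 40_000
        for _ in range(draws):
            counts[tournament_select(pop, rng).fitness] += 1
        for k, f in enumerate(fitnesses, start=1):
            expected = (2 * (n - k) + 1) / n**2
            assert counts[f] / draws == pytest.approx(expected, abs=0.01)

    def test_unevaluated_individual_rejected(self):
        pop = [Individual(Genome(0, (10.0,) * 4))] * 2
        with pytest.raises(ValueError):
            tournament_select(pop, np.random.default_rng(0))


class TestInitPopulation:
    def test_seeded_determinism_and_bounds(self, quarter_scale_frame):
        S, _, _ = quarter_scale_frame
        cfg = GAConfig(population_size=30, length_min=10, length_max=80)
        p1 = init_population(S, cfg, np.random.default_rng(5))
        p2 = init_population(S, cfg, np.random.default_rng(5))
        n_cand = len(uppermost_candidates(S, cfg.top_fraction))
        assert all(a.genome == b.genome for a, b in zip(p1, p2))
        for ind in p1:
            assert 0 <= ind.genome.pixel_index < n_cand
            assert all(10 <= l <= 80 for l in ind.genome.lengths)

    def test_uniform_length_moments(self, quarter_scale_frame):
        S, _, _ = quarter_scale_frame
        cfg = GAConfig(population_size=10_000, length_min=10, length_max=90)
        pop = init_population(S, cfg, np.random.default_rng(77))
        lens = np.array([ind.genome.lengths for ind in pop]).ravel()
        se = (90 - 10) / math.sqrt(12) / math.sqrt(lens.size)
        assert abs(lens.mean() - 50.0) < 3 * se


class TestEvaluate:
    def test_truth_genome_scores_high(self, quarter_scale_frame):
        S, model, _ = quarter_scale_frame
        cfg = GAConfig(population_size=4, local_search=SMALL_LS)
        cands = uppermost_candidates(S, cfg.top_fraction)
        d = np.abs(cands[:, 1] - model.x1) + np.abs(cands[:, 0] - model.y1)
        ind = Individual(Genome(int(np.argmin(d)), tuple(model.lengths)))
        evaluate(ind, S, cfg, cands)
        assert ind.fitness >= 0.99

    def test_fitness_in_unit_interval_and_deterministic(self, quarter_scale_frame):
        S, _, _ = quarter_scale_frame
        cfg = GAConfig(population_size=4, local_search=SMALL_LS)
        cands = uppermost_candidates(S, cfg.top_fraction)
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = Genome(int(rng.integers(0, len(cands))), tuple(rng.uniform(10, 60, 4)))
            a = evaluate(Individual(g), S, cfg, cands).fitness
            b = evaluate(Individual(g), S, cfg, cands).fitness
            assert 0.0 <= a <= 1.0
            assert a == b


class TestFitFrame:
    def test_elite_history_monotone_and_reproducible(self, quarter_scale_frame):
        S, _, _ = quarter_scale_frame
        cfg = GAConfig(population_size=12, max_generations=6, local_search=SMALL_LS)
        r1 = fit_frame(S, cfg, rng=99)
        r2 = fit_frame(S, cfg, rng=99)
        assert np.all(np.diff(r1.elite_history) >= 0)
        assert r1.elite_history == r2.elite_history
        assert np.array_equal(
            np.concatenate([[r1.model.x1, r1.model.y1], r1.model.lengths,
                            r1.model.thetas, r1.model.widths]),
            np.concatenate([[r2.model.x1, r2.model.y1], r2.model.lengths,
                            r2.model.thetas, r2.model.widths]),
        )

    def test_constant_landscape_stops_after_nmaxelite_plus_one(self):
        # a single white pixel far from everything: every genome fails
        # identically once the start candidate is fixed, so the elite
        # never improves after generation 1
        S = np.zeros((40, 40), dtype=bool)
        S[5, 20] = True
        S[6, 20] = True
        cfg = GAConfig(population_size=6, n_maxelite=3, max_generations=50,
                       local_search=SMALL_LS)
        res = fit_frame(S, cfg, rng=0)
        assert res.stop_reason == "no_improvement"
        # the elite can improve during early generations; once flat, the
        # run ends n_maxelite + 1 generations after the last improvement
        hist = np.array(res.elite_history)
        last_improvement = int(np.flatnonzero(np.diff(hist) > 0)[-1] + 1) if np.any(
            np.diff(hist) > 0) else 0
        assert res.generations == last_improvement + cfg.n_maxelite + 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fit_frame(np.zeros((20, 20), dtype=bool), GAConfig(population_size=4))

    def test_recovers_ground_truth_model(self, quarter_scale_frame):
        S, model, _ = quarter_scale_frame
        cfg = GAConfig(population_size=40, local_search=SMALL_LS)
        res = fit_frame(S, cfg, rng=2)
        assert res.fitness > 0.99
        assert np.abs(wrap_angle(res.model.thetas - model.thetas)).max() <= 0.06
        assert np.abs(res.model.lengths - model.lengths).max() <= 6
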