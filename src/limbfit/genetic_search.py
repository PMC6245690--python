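"""Elitist genetic algorithm over the start pixel and segment lengths.

The global and the local optimizers own disjoint variables: the GA
evolves a five-gene chromosome (the index of a candidate start pixel
among the uppermost marker pixels, plus the four segment lengths),
while evaluating a chromosome *is* the deterministic local search that
finds the four angles and widths for it.  Fitness is the accuracy of
the completed 14-parameter model against the marker mask.

Operators are the real-coded classics: binary tournament selection,
simulated binary crossover (SBX) and polynomial mutation, with a small
elite copied unchanged each generation.  The run stops once the elite
has failed to improve for ``n_maxelite`` consecutive generations (or at
a safety cap on generations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import uppermost_candidates
from .kinematics import LimbModel, wrap_angle
from .local_search import LocalSearchConfig, LocalSearchResult, local_search

__all__ = [
    "Genome",
    "Individual",
    "GAConfig",
    "FitResult",
    "sbx_values",
    "sbx_crossover",
    "mutation_delta",
    "polynomial_mutation",
    "tournament_select",
    "init_population",
    "evaluate",
    "fit_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Genome:
    """GA chromosome: start-pixel index plus the four segment lengths."""

    pixel_index: int
    lengths: tuple[float, float, float, float]

    def key(self) -> tuple:
        return (self.pixel_index, *self.lengths)


@dataclass
class Individual:
    genome: Genome
    fitness: float | None = None
    result: LocalSearchResult | None = None


@dataclass
class GAConfig:
    """GA parameters.

    Defaults follow the reported experimental setup: population 400,
    crossover probability 0.9, per-gene mutation probability 0.11,
    3 elites, stop after 8 stagnant generations, SBX index 1.  The
    mutation distribution index is a conventional default (20).
    ``length_max=None`` means half the image diagonal.
    """

    population_size: int = 400
    crossover_prob: float = 0.9
    mutation_prob: float = 0.11
    eta_c: float = 1.0
    eta_m: float = 20.0
    n_elite: int = 3
    n_maxelite: int = 8
    max_generations: int = 100
    length_min: float = 10.0
    length_max: float | None = None
    top_fraction: float = 0.05
    local_search: LocalSearchConfig = field(default_factory=LocalSearchConfig)

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not (0 <= self.n_elite < self.population_size):
            raise ValueError("need 0 <= n_elite < population_size")
        if self.n_maxelite < 1 or self.max_generations < 1:
            raise ValueError("n_maxelite and max_generations must be positive")


@dataclass
class FitResult:
    """Best model found for one frame plus convergence metadata."""

    model: LimbModel
    fitness: float
    generations: int
    evaluations: int
    stop_reason: str
    converged: bool
    elite_history: list[float] = field(default_factory=list)


def sbx_values(x1: float, x2: float, u: float, eta_c: float) -> tuple[float, float]:
    """Simulated binary crossover of two scalar genes for a given draw u.

    The spread factor is ``beta = (2u)^(1/(eta_c+1))`` for u < 0.5 and
    ``(1/(2(1-u)))^(1/(eta_c+1))`` otherwise; the children are
    ``((x1+x2) -/+ beta (x2-x1)) / 2``, so their sum always equals the
    parents' sum and u = 0.5 reproduces the parents.
    """
    if u < 0.5:
        beta = (2.0 * u) ** (1.0 / (eta_c + 1.0))
    else:
        beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta_c + 1.0))
    s, d = x1 + x2, x2 - x1
    return 0.5 * (s - beta * d), 0.5 * (s + beta * d)


def _round_index(x: float, n_candidates: int) -> int:
    return int(min(max(math.floor(x + 0.5), 0), n_candidates - 1))


def sbx_crossover(
    parent1: Genome,
    parent2: Genome,
    eta_c: float,
    rng: np.random.Generator,
    length_bounds: tuple[float, float],
    n_candidates: int,
) -> tuple[Genome, Genome]:
    """Gene-wise SBX on the index and the four lengths.

    Each gene gets its own uniform draw.  Lengths are clamped to their
    bounds; the pixel index is treated as continuous during the
    arithmetic, then rounded half-up and clamped.
    """
    lo, hi = length_bounds
    p1 = np.array([parent1.pixel_index, *parent1.lengths], dtype=float)
    p2 = np.array([parent2.pixel_index, *parent2.lengths], dtype=float)
    c1 = np.empty(5)
    c2 = np.empty(5)
    for g in range(5):
        c1[g], c2[g] = sbx_values(p1[g], p2[g], float(rng.random()), eta_c)
    l1 = tuple(np.clip(c1[1:], lo, hi))
    l2 = tuple(np.clip(c2[1:], lo, hi))
    return (
        Genome(_round_index(c1[0], n_candidates), l1),
        Genome(_round_index(c2[0], n_candidates), l2),
    )


def mutation_delta(u: float, eta_m: float) -> float:
    """Inverse-CDF draw of the polynomial-mutation perturbation.

    delta in (-1, 1) follows the density
    ``P(delta) = 0.5 (eta_m + 1) (1 - |delta|)^eta_m``.
    """
    if u < 0.5:
        return (2.0 * u) ** (1.0 / (eta_m + 1.0)) - 1.0
    return 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta_m + 1.0))


def polynomial_mutation(
    genome: Genome,
    config: GAConfig,
    rng: np.random.Generator,
    length_bounds: tuple[float, float],
    n_candidates: int,
) -> Genome:
    """Mutate each gene independently with probability ``mutation_prob``.

    The perturbation is ``delta * (upper - lower)`` of the gene's own
    bounds, then clamped (and rounded for the index gene).
    """
    lo, hi = length_bounds
    idx = float(genome.pixel_index)
    if rng.random() < config.mutation_prob:
        delta = mutation_delta(float(rng.random()), config.eta_m)
        idx += delta * (n_candidates - 1)
    lengths = list(genome.lengths)
    for g in range(4):
        if rng.random() < config.mutation_prob:
            delta = mutation_delta(float(rng.random()), config.eta_m)
            lengths[g] = min(max(lengths[g] + delta * (hi - lo), lo), hi)
    return Genome(_round_index(idx, n_candidates), tuple(lengths))


def tournament_select(population: list[Individual], rng: np.random.Generator) -> Individual:
    """Binary tournament: draw two (with replacement), keep the fitter.

    Ties are broken uniformly at random.
    """
    i, j = rng.integers(0, len(population), size=2)
    a, b = population[int(i)], population[int(j)]
    if a.fitness is None or b.fitness is None:
        raise ValueError("tournament selection requires evaluated individuals")
    if a.fitness > b.fitness:
        return a
    if b.fitness > a.fitness:
        return b
    return a if rng.random() < 0.5 else b


def init_population(
    S: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    candidates: np.ndarray | None = None,
) -> list[Individual]:
    """Uniform random population over the candidate indices and length box."""
    if candidates is None:
        candidates = uppermost_candidates(S, config.top_fraction)
    if len(candidates) == 0:
        raise ValueError("no candidate start pixels")
    lo, hi = _length_bounds(S, config)
    idx = rng.integers(0, len(candidates), size=config.population_size)
    lens = rng.uniform(lo, hi, size=(config.population_size, 4))
    return [
        Individual(Genome(int(idx[k]), tuple(lens[k])))
        for k in range(config.population_size)
    ]


def _length_bounds(S: np.ndarray, config: GAConfig) -> tuple[float, float]:
    if config.length_max is not None:
        return (config.length_min, config.length_max)
    h, w = S.shape
    return (config.length_min, 0.5 * math.hypot(w, h))


def evaluate(
    individual: Individual,
    S: np.ndarray,
    config: GAConfig,
    candidates: np.ndarray,
) -> Individual:
    """Complete a chromosome via the local search and set its fitness.

    The candidate pixel index is decoded to the start point, the local
    search supplies angles and widths, and the fitness is the accuracy
    of the completed model.  A failing local search yields fitness 0
    with a logged diagnostic rather than an exception.
    """
    row, col = candidates[individual.genome.pixel_index]
    try:
        res = local_search(
            S, (float(col), float(row)), np.asarray(individual.genome.lengths),
            config=config.local_search,
        )
        # Selection ranks by the penalized objective; it equals the plain
        # accuracy whenever the model stays inside the frame.
        individual.fitness = float(res.objective)
        individual.result = res
    except Exception:  # pragma: no cover - defensive
        logger.exception("local search failed for genome %s", individual.genome)
        individual.fitness = 0.0
        individual.result = None
    return individual


def fit_frame(
    S: np.ndarray,
    config: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    convergence_threshold: float = 0.5,
    evaluation_cache: dict | None = None,
) -> FitResult:
    """Fit the full 14-parameter model to one marker mask.

    Runs the elitist GA (selection, SBX, polynomial mutation) with the
    local search as the evaluation step and returns the best-ever
    individual as a complete :class:`~limbfit.kinematics.LimbModel`.
    Fully reproducible for a fixed seed.

    ``evaluation_cache`` may be shared between repeated executions on
    the *same* mask and configuration: evaluation is deterministic, so
    memoizing it across runs changes no result, only the runtime of
    the multiple-independent-executions protocol.
    """
    cfg = config or GAConfig()
    rng = np.random.default_rng(rng)
    S = np.asarray(S, dtype=bool)
    if not S.any():
        raise ValueError("mask contains no marker pixels")
    candidates = uppermost_candidates(S, cfg.top_fraction)
    length_bounds = _length_bounds(S, cfg)
    n_cand = len(candidates)

    cache: dict[tuple, tuple[float, LocalSearchResult | None]]
    cache = evaluation_cache if evaluation_cache is not None else {}
    evaluations = 0

    def eval_ind(ind: Individual) -> None:
        nonlocal evaluations
        if ind.fitness is not None:
            return
        hit = cache.get(ind.genome.key())
        if hit is not None:
            ind.fitness, ind.result = hit
            return
        evaluate(ind, S, cfg, candidates)
        cache[ind.genome.key()] = (ind.fitness, ind.result)
        evaluations += 1

    population = init_population(S, cfg, rng, candidates)
    for ind in population:
        eval_ind(ind)
    population.sort(key=lambda i: -i.fitness)
    best = population[0]
    history = [best.fitness]
    streak = 0
    generation = 0
    stop_reason = "max_generations"

    while generation < cfg.max_generations:
        generation += 1
        next_pop = [Individual(e.genome, e.fitness, e.result)
                    for e in population[: cfg.n_elite]]
        while len(next_pop) < cfg.population_size:
            p1 = tournament_select(population, rng)
            p2 = tournament_select(population, rng)
            if rng.random() < cfg.crossover_prob:
                g1, g2 = sbx_crossover(p1.genome, p2.genome, cfg.eta_c, rng,
                                       length_bounds, n_cand)
            else:
                g1, g2 = p1.genome, p2.genome
            for g in (g1, g2):
                if len(next_pop) < cfg.population_size:
                    mutated = polynomial_mutation(g, cfg, rng, length_bounds, n_cand)
                    next_pop.append(Individual(mutated))
        for ind in next_pop:
            eval_ind(ind)
        next_pop.sort(key=lambda i: -i.fitness)
        population = next_pop
        if population[0].fitness > best.fitness:
            best = population[0]
            streak = 0
        else:
            streak += 1
        history.append(best.fitness)
        logger.debug("generation %d elite fitness %.6f evaluations %d",
                     generation, best.fitness, evaluations)
        if streak > cfg.n_maxelite:
            stop_reason = "no_improvement"
            break

    row, col = candidates[best.genome.pixel_index]
    res = best.result
    model = LimbModel(
        x1=float(col), y1=float(row),
        lengths=np.asarray(best.genome.lengths),
        thetas=wrap_angle(res.thetas),
        widths=res.widths,
    )
    converged = not (stop_reason == "max_generations"
                     and best.fitness < convergence_threshold)
    final_score = float(res.score) if res is not None else float(best.fitness)
    return FitResult(
        model=model, fitness=final_score, generations=generation,
        evaluations=evaluations, stop_reason=stop_reason, converged=converged,
        elite_history=history,
    )
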