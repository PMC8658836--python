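"""Search strategies over a discrete hyperparameter space.

Four strategies share one interface: given a space and a fitness callable
(configuration -> NER_T in [0, 100]), each returns a :class:`RunHistory`
with one record per fitness evaluation.

* grid search — exhaustive, one evaluation per grid point;
* random search — a fixed budget of distinct uniform draws (default 100);
* genetic algorithm — 10 binary chromosomes evolved for 42 generations
  with roulette-wheel selection, one-point crossover, 10% per-bit
  mutation, culling of the two worst after every generation, and a
  cataclysm at generation 21 that replaces the worst half of the
  population with fresh random chromosomes; the run consumes exactly 100
  fitness evaluations;
* tree-structured Parzen estimator — sequential model-based optimization
  with categorical Parzen densities over the good and bad halves of the
  observation history, 100 trials.

Duplicate configurations are re-scored from a cache but still consume
budget: the budget counts trials, not unique points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .search_space import (
    ArchitectureConfig,
    Chromosome,
    HyperparameterSpace,
    decode,
    enumerate_grid,
    random_chromosome,
    sample_random,
)

__all__ = [
    "EvaluationRecord",
    "RunHistory",
    "grid_search",
    "random_search",
    "ga_optimize",
    "tpe_optimize",
    "roulette_select",
    "mutate",
    "crossover_one_point",
]

Fitness = Callable[[ArchitectureConfig], float]


@dataclass(frozen=True)
class EvaluationRecord:
    index: int
    config: ArchitectureConfig
    fitness: float
    method: str
    replicate: int = 0
    generation: int | None = None
    in_final_population: bool = False


@dataclass
class RunHistory:
    """Ordered record of every evaluated configuration in one run."""

    method: str
    records: list[EvaluationRecord] = field(default_factory=list)
    replicate: int = 0

    def append(
        self,
        config: ArchitectureConfig,
        fitness: float,
        generation: int | None = None,
    ) -> EvaluationRecord:
        rec = EvaluationRecord(
            len(self.records), config, float(fitness), self.method,
            self.replicate, generation,
        )
        self.records.append(rec)
        return rec

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best(self) -> EvaluationRecord:
        return max(self.records, key=lambda r: r.fitness)

    def best_so_far(self) -> np.ndarray:
        return np.maximum.accumulate([r.fitness for r in self.records])

    def flag_final_population(self, configs: list[ArchitectureConfig]) -> None:
        """Mark the most recent record of each final-population member."""
        remaining = list(configs)
        for i in range(len(self.records) - 1, -1, -1):
            rec = self.records[i]
            if rec.config in remaining:
                remaining.remove(rec.config)
                self.records[i] = EvaluationRecord(
                    rec.index, rec.config, rec.fitness, rec.method,
                    rec.replicate, rec.generation, True,
                )
            if not remaining:
                break

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "evaluation": r.index,
                "method": r.method,
                "replicate": r.replicate,
                "generation": r.generation,
                "fitness": r.fitness,
                "in_final_population": r.in_final_population,
            }
            row.update(r.config.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


class _CachedFitness:
    """Caches fitness by configuration; repeats cost budget, not compute."""

    def __init__(self, fitness: Fitness):
        self._fitness = fitness
        self._cache: dict[ArchitectureConfig, float] = {}

    def __call__(self, config: ArchitectureConfig) -> float:
        if config not in self._cache:
            self._cache[config] = float(self._fitness(config))
        return self._cache[config]


# ---------------------------------------------------------------------------
# exhaustive and random search


def grid_search(
    space: HyperparameterSpace, fitness: Fitness, replicate: int = 0
) -> RunHistory:
    """Evaluate every grid point once, in deterministic order."""
    history = RunHistory("gs", replicate=replicate)
    for config in enumerate_grid(space):
        history.append(config, fitness(config))
    return history


def random_search(
    space: HyperparameterSpace,
    fitness: Fitness,
    n: int = 100,
    seed: int | np.random.Generator = 0,
    replicate: int = 0,
) -> RunHistory:
    """Evaluate ``n`` distinct uniform draws from the grid."""
    history = RunHistory("rs", replicate=replicate)
    for config in sample_random(space, n, seed):
        history.append(config, fitness(config))
    return history


# ---------------------------------------------------------------------------
# genetic algorithm


def roulette_select(
    population: list[tuple[Chromosome, float]], rng: np.random.Generator
) -> Chromosome:
    """Fitness-proportional selection; uniform if all fitnesses are zero."""
    fit = np.array([f for _, f in population], dtype=float)
    if np.any(fit < 0):
        raise ValueError("roulette selection requires non-negative fitness")
    total = fit.sum()
    if total <= 0:
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = fit / total
    i = int(rng.choice(len(population), p=probs))
    return population[i][0]


def mutate(chrom: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    flips = rng.random(len(chrom)) < rate
    return Chromosome(
        tuple(b ^ int(f) for b, f in zip(chrom.bits, flips))
    )


def crossover_one_point(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover at a uniform random cut (1..L-1)."""
    if len(a) != len(b):
        raise ValueError("parents must have equal length")
    cut = int(rng.integers(1, len(a)))
    return (
        Chromosome(a.bits[:cut] + b.bits[cut:]),
        Chromosome(b.bits[:cut] + a.bits[cut:]),
    )


def ga_optimize(
    space: HyperparameterSpace,
    fitness: Fitness,
    seed: int | np.random.Generator = 0,
    population_size: int = 10,
    generations: int = 42,
    mutation_rate: float = 0.10,
    cataclysm_at: int = 21,
    budget: int = 100,
    replicate: int = 0,
) -> RunHistory:
    """Small-budget genetic algorithm over binary chromosomes.

    Per generation, two parents are drawn by roulette wheel, recombined by
    one-point crossover, mutated bitwise, evaluated and inserted, and the
    two worst members are culled.  At the cataclysm generation the worst
    half of the population is additionally replaced by fresh random
    chromosomes.  The nominal accounting (10 initial + 2 x 42 children + 5
    cataclysm = 99) is topped up with uniform random probes so that the
    run consumes exactly ``budget`` evaluations; the history's final
    ``population_size`` members are flagged.
    """
    if population_size % 2 != 0:
        raise ValueError("population size must be even")
    if budget < population_size:
        raise ValueError("budget must cover the initial population")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cached = _CachedFitness(fitness)
    history = RunHistory("ga", replicate=replicate)

    def evaluate(chrom: Chromosome, generation: int | None) -> float:
        config = decode(chrom, space)
        f = cached(config)
        history.append(config, f, generation)
        return f

    population: list[tuple[Chromosome, float]] = []
    for _ in range(population_size):
        c = random_chromosome(space, rng)
        population.append((c, evaluate(c, 0)))

    for gen in range(1, generations + 1):
        if len(history) + 2 > budget:
            break
        p1 = roulette_select(population, rng)
        p2 = roulette_select(population, rng)
        c1, c2 = crossover_one_point(p1, p2, rng)
        c1 = mutate(c1, mutation_rate, rng)
        c2 = mutate(c2, mutation_rate, rng)
        population.append((c1, evaluate(c1, gen)))
        population.append((c2, evaluate(c2, gen)))
        # cull the two worst (ties broken by insertion order: earliest goes)
        for _ in range(2):
            worst = min(range(len(population)), key=lambda i: population[i][1])
            population.pop(worst)
        if gen == cataclysm_at:
            n_replace = population_size // 2
            if len(history) + n_replace > budget:
                break
            order = sorted(range(len(population)), key=lambda i: population[i][1])
            survivors = [population[i] for i in order[n_replace:]]
            invaders = []
            for _ in range(n_replace):
                c = random_chromosome(space, rng)
                invaders.append((c, evaluate(c, gen)))
            population = survivors + invaders

    # top up to the exact budget with uniform random probes
    while len(history) < budget:
        c = random_chromosome(space, rng)
        evaluate(c, None)

    history.flag_final_population([decode(c, space) for c, _ in population])
    return history


# ---------------------------------------------------------------------------
# tree-structured Parzen estimator


def _categorical_densities(
    configs: list[ArchitectureConfig], space: HyperparameterSpace
) -> dict[str, np.ndarray]:
    """Per-factor smoothed level densities (+1 pseudo-count, normalised)."""
    out = {}
    for f in space.factors:
        counts = np.ones(f.n_levels)  # Laplace prior
        for c in configs:
            counts[f.level_index(c[f.name])] += 1
        out[f.name] = counts / counts.sum()
    return out


def tpe_optimize(
    space: HyperparameterSpace,
    fitness: Fitness,
    seed: int | np.random.Generator = 0,
    n_trials: int = 100,
    n_startup: int = 10,
    gamma: float = 0.25,
    n_candidates: int = 24,
    replicate: int = 0,
) -> RunHistory:
    """Sequential model-based optimization with categorical Parzen densities.

    After ``n_startup`` random trials, the observations are sorted by score
    and split into the best ceil(gamma*n) (modelled by density l) and the
    rest (density g).  Each trial draws ``n_candidates`` configurations
    factor-wise from l and sends the one maximising l(x)/g(x) — the
    greatest expected improvement — to the true fitness.
    """
    if n_trials < n_startup:
        raise ValueError("n_trials must be >= n_startup")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cached = _CachedFitness(fitness)
    history = RunHistory("tpe", replicate=replicate)

    observations: list[tuple[ArchitectureConfig, float]] = []
    for config in sample_random(space, min(n_startup, n_trials), rng):
        f = cached(config)
        history.append(config, f)
        observations.append((config, f))

    while len(history) < n_trials:
        order = sorted(
            range(len(observations)),
            key=lambda i: observations[i][1],
            reverse=True,
        )
        n_good = math.ceil(gamma * len(observations))
        good = [observations[i][0] for i in order[:n_good]]
        bad = [observations[i][0] for i in order[n_good:]]
        l_dens = _categorical_densities(good, space)
        g_dens = _categorical_densities(bad, space)

        best_cfg, best_ratio = None, -np.inf
        for _ in range(n_candidates):
            values, log_ratio = {}, 0.0
            for f in space.factors:
                idx = int(rng.choice(f.n_levels, p=l_dens[f.name]))
                values[f.name] = f.levels[idx]
                log_ratio += math.log(l_dens[f.name][idx]) - math.log(
                    g_dens[f.name][idx]
                )
            if log_ratio > best_ratio:
                best_ratio = log_ratio
                best_cfg = ArchitectureConfig.from_mapping(values)
        assert best_cfg is not None
        f_val = cached(best_cfg)
        history.append(best_cfg, f_val)
        observations.append((best_cfg, f_val))
    return history
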