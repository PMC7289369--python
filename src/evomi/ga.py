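"""Generic genetic-algorithm loop shared by all three searches.

One engine drives wrapper feature selection, structure search, and
learning-parameter search: binary tournament selection, generational
offspring production, and elitist merge-truncate replacement.  Fitness is
the 5-fold cross-validated accuracy of a classifier built from the genome;
each distinct genome is evaluated once and cached, so recorded fitness is
deterministic per genome and the best fitness never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Individual",
    "GAConfig",
    "GAResult",
    "binary_tournament",
    "elitist_replacement",
    "evolve",
    "kfold_cv_fitness",
]


@dataclass
class Individual:
    genome: object
    fitness: float | None = None


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 10
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    seed: int = 0
    cv_folds: int = 5
    cv_repeats: int = 1  # CV repetitions averaged per fitness evaluation

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class GAResult:
    best_individual: Individual
    best_fitness_per_generation: list[float]
    mean_fitness_per_generation: list[float]
    final_population: list[Individual]
    evaluations: int

    @property
    def best_fitness(self) -> float:
        return float(self.best_individual.fitness)


def binary_tournament(population: Sequence[Individual], rng: np.random.Generator) -> Individual:
    """Draw two individuals uniformly with replacement, keep the fitter.

    Fitness ties are broken uniformly at random.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    i, j = rng.integers(0, len(population), size=2)
    a, b = population[i], population[j]
    if a.fitness > b.fitness:
        return a
    if b.fitness > a.fitness:
        return b
    return a if rng.random() < 0.5 else b


def elitist_replacement(
    population: Sequence[Individual],
    offspring: Sequence[Individual],
    target_size: int,
) -> list[Individual]:
    """Rank the union by fitness (descending, stable) and truncate.

    The stable sort breaks ties by insertion order — current population
    before offspring — so an offspring must strictly beat an incumbent to
    displace it.
    """
    union = list(population) + list(offspring)
    if target_size > len(union):
        raise ValueError("target_size exceeds union of population and offspring")
    if any(ind.fitness is None for ind in union):
        raise ValueError("all fitnesses must be evaluated before replacement")
    ranked = sorted(union, key=lambda ind: -ind.fitness)
    return ranked[:target_size]


def _genome_key(genome) -> object:
    arr = np.asarray(genome)
    return (arr.dtype.kind, arr.shape, arr.tobytes())


def evolve(
    initial_genomes: Sequence[object],
    fitness_fn: Callable[[object], float],
    crossover: Callable[[object, object, np.random.Generator], object],
    mutate: Callable[[object, np.random.Generator], object],
    config: GAConfig,
    repair: Callable[[object, np.random.Generator], object] | None = None,
) -> GAResult:
    """Run the generational GA with elitist replacement.

    Per generation, ``population_size`` offspring are produced: two parents
    via binary tournament, crossover applied with ``crossover_prob`` (else
    the first parent is copied), mutation with ``mutation_prob``, then an
    optional repair.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[object, float] = {}
    evaluations = 0

    def evaluate(genome) -> float:
        nonlocal evaluations
        key = _genome_key(genome)
        if key not in cache:
            value = float(fitness_fn(genome))
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"fitness {value} outside [0, 1]")
            cache[key] = value
            evaluations += 1
        return cache[key]

    population = [Individual(g, evaluate(g)) for g in initial_genomes]
    best_series: list[float] = []
    mean_series: list[float] = []

    for _ in range(config.generations):
        offspring = []
        for _ in range(config.population_size):
            p1 = binary_tournament(population, rng)
            p2 = binary_tournament(population, rng)
            if rng.random() < config.crossover_prob:
                child = crossover(p1.genome, p2.genome, rng)
            else:
                child = np.array(p1.genome, copy=True)
            if rng.random() < config.mutation_prob:
                child = mutate(child, rng)
            if repair is not None:
                child = repair(child, rng)
            offspring.append(Individual(child, evaluate(child)))
        population = elitist_replacement(population, offspring, config.population_size)
        best_series.append(population[0].fitness)
        mean_series.append(float(np.mean([ind.fitness for ind in population])))

    return GAResult(
        best_individual=population[0],
        best_fitness_per_generation=best_series,
        mean_fitness_per_generation=mean_series,
        final_population=population,
        evaluations=evaluations,
    )


def kfold_cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[], object],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy over stratified k folds.

    The factory must return a fresh unfitted classifier with ``fit`` and
    ``predict``; sklearn estimators are cloned defensively.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise ValueError(f"every class needs at least k={k} members for k-fold CV")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(X, y):
        model = model_factory()
        try:
            model = clone(model)
        except TypeError:
            pass
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx]))
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))
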