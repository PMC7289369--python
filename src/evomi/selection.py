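"""GA wrapper feature selection with a binary mask genome.

Each individual is one bit per feature (1 = active).  Fitness is the
cross-validated accuracy of a light classifier (logistic regression by
default) trained on the active columns.  A hard cap on the number of active
features (default 30) is enforced by repair after every crossover and
mutation; initial active counts are drawn uniformly from [1, max_active].
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted, validate_data

from .ga import GAConfig, GAResult, evolve, kfold_cv_fitness

__all__ = [
    "init_fs_population",
    "uniform_crossover",
    "bit_flip_mutation",
    "repair_constraint",
    "run_feature_selection",
    "GeneticFeatureSelector",
]


def init_fs_population(
    n: int, n_features: int, max_active: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random masks whose active counts are uniform on [1, max_active]."""
    if max_active < 1 or max_active > n_features:
        raise ValueError("max_active must be in [1, n_features]")
    if n < 2:
        raise ValueError("population size must be >= 2")
    population = []
    for _ in range(n):
        k = int(rng.integers(1, max_active + 1))
        mask = np.zeros(n_features, dtype=bool)
        mask[rng.choice(n_features, size=k, replace=False)] = True
        population.append(mask)
    return population


def uniform_crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Copy every bit the parents share; randomize the rest 50/50."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parent masks must have equal length")
    child = a.copy()
    differ = a != b
    child[differ] = rng.random(differ.sum()) < 0.5
    return child


def bit_flip_mutation(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Invert exactly one uniformly chosen bit."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask is empty")
    out = mask.copy()
    pos = int(rng.integers(mask.size))
    out[pos] = ~out[pos]
    return out


def repair_constraint(
    mask: np.ndarray, max_active: int, rng: np.random.Generator
) -> np.ndarray:
    """Enforce 1 <= active_count <= max_active.

    Excess active bits are cleared uniformly at random (survivors are a
    subset of the originals); an all-zero mask gets one uniformly chosen
    active bit.
    """
    if max_active < 1:
        raise ValueError("max_active must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    active = np.flatnonzero(out)
    if active.size > max_active:
        drop = rng.choice(active, size=active.size - max_active, replace=False)
        out[drop] = False
    elif active.size == 0:
        out[int(rng.integers(out.size))] = True
    return out


def _default_fs_classifier() -> LogisticRegression:
    # Light wrapped model: many fitness evaluations must stay cheap.
    return LogisticRegression(max_iter=200)


def run_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    classifier_factory: Callable[[], object] | None = None,
    config: GAConfig | None = None,
    max_active: int = 30,
) -> tuple[np.ndarray, GAResult]:
    """Run the GA wrapper search; returns (best mask, GA trajectory)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or GAConfig(population_size=1000, generations=100)
    factory = classifier_factory or _default_fs_classifier
    rng = np.random.default_rng(config.seed)
    initial = init_fs_population(config.population_size, X.shape[1], max_active, rng)

    def fitness(mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        return kfold_cv_fitness(X[:, cols], y, factory, k=config.cv_folds, seed=config.seed)

    result = evolve(
        initial,
        fitness,
        crossover=uniform_crossover,
        mutate=bit_flip_mutation,
        config=config,
        repair=lambda m, r: repair_constraint(m, max_active, r),
    )
    return np.asarray(result.best_individual.genome, dtype=bool), result


class GeneticFeatureSelector(SelectorMixin, BaseEstimator):
    """Sklearn transformer wrapping the GA feature-subset search.

    Parameters
    ----------
    max_active : hard cap on selected features (default 30).
    population_size, generations : GA budget (study defaults 1000 / 100).
    estimator : unfitted classifier evaluated by CV on candidate subsets;
        defaults to logistic regression.
    cv : folds for the fitness cross-validation.
    random_state : seed controlling the whole search.

    Attributes
    ----------
    support_ : boolean mask of selected features.
    ga_result_ : the GA trajectory (best fitness per generation, etc.).
    """

    def __init__(
        self,
        max_active: int = 30,
        population_size: int = 1000,
        generations: int = 100,
        crossover_prob: float = 0.9,
        mutation_prob: float = 0.1,
        estimator=None,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.max_active = max_active
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        config = GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            seed=self.random_state,
            cv_folds=self.cv,
        )
        est = self.estimator
        factory = (lambda: est) if est is not None else None
        mask, result = run_feature_selection(
            X, y, classifier_factory=factory, config=config, max_active=self.max_active
        )
        self.support_ = mask
        self.ga_result_ = result
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
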