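"""Two-step evolutionary hyperparameter optimization.

Step 1 searches the structural hyperparameters of a network family (number
and size of filters for the CNN, hidden-layer widths for the FFNN, GRU
units for the RNN) with fixed baseline training parameters (60 epochs,
learning rate 0.1).  Step 2 freezes the best structure and searches the
learning hyperparameters (learning rate, epochs, and — for the FFNN —
dropout rate).  Both steps share the generic GA engine with 5-fold
cross-validated accuracy as fitness; the study budget is 40 individuals
over 10 generations per step.

Genomes are real-coded.  Initial genes are drawn from a normal centered at
the middle of the allowed range with SD range/6 (so ±3 SD spans the
range), clamped, rounded for integer genes, and filter sizes forced odd.
Gaussian mutation multiplies one gene by a draw from Normal(1, sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .ga import GAConfig, GAResult, evolve, kfold_cv_fitness
from .networks import (
    CNNSpec,
    FFNNSpec,
    RNNSpec,
    TrainingParams,
    build_model,
)


def _safe_cv_fitness(X, y, factory, k, seed, repeats: int = 1) -> float:
    """CV accuracy averaged over ``repeats`` fold seeds.

    Candidates whose training diverges (non-finite loss) score 0; averaging
    over more than one CV repetition lowers the noise of the fitness
    estimate, which otherwise inflates the apparent quality of the search
    winner.
    """
    try:
        scores = [
            kfold_cv_fitness(X, y, factory, k=k, seed=seed + r)
            for r in range(max(1, repeats))
        ]
        return float(np.mean(scores))
    except FloatingPointError:
        return 0.0

__all__ = [
    "STRUCTURE_BOUNDS",
    "ModelSpec",
    "init_structure_population",
    "single_point_crossover",
    "gaussian_mutation",
    "midpoint_crossover",
    "ffnn_mutation",
    "optimize_structure",
    "optimize_learning",
    "two_step_optimize",
    "TwoStepSearch",
]

# (low, high, integer?) per gene; FFNN widths are uncapped in the search,
# the high bound here only shapes initialization (init cap 200 per layer).
STRUCTURE_BOUNDS = {
    "cnn": [(1, 250, True), (1, 19, True)],  # n_filters, filter_size (odd)
    "rnn": [(1, 60, True)],  # gru_units
    "ffnn": [(1, 200, True)],  # per-layer width (depth 1 or 2)
}

# Learning-genome bounds: learning rate, epochs, dropout (ffnn only).
LEARNING_BOUNDS = {
    "lr": (1e-4, 1.0, False),
    "epochs": (1, 200, True),
    "dropout": (0.0, 0.9, False),
}

BASELINE_TRAINING = TrainingParams(learning_rate=0.1, epochs=60)

# Unoptimized reference structures used in the study's baseline tables.
BASELINE_STRUCTURES = {"cnn": (130, 5), "ffnn": (100,), "rnn": (16,)}

DEFAULT_ACTIVATIONS = {"cnn": "relu", "ffnn": "elu", "rnn": "relu"}


@dataclass
class ModelSpec:
    """Fully decoded model: family, structure, and training parameters."""

    family: str
    structure: tuple
    training: TrainingParams
    activation: str = ""
    seed: int = 0
    structure_result: GAResult | None = field(default=None, repr=False)
    learning_result: GAResult | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.activation:
            self.activation = DEFAULT_ACTIVATIONS[self.family]

    def network_spec(self, n_inputs: int, n_classes: int):
        if self.family == "cnn":
            return CNNSpec(
                int(self.structure[0]), int(self.structure[1]),
                n_inputs, n_classes, self.activation,
            )
        if self.family == "ffnn":
            return FFNNSpec(
                tuple(int(w) for w in self.structure), n_inputs, n_classes,
                self.activation, self.training.dropout_rate,
            )
        if self.family == "rnn":
            return RNNSpec(int(self.structure[0]), n_inputs, n_classes, self.activation)
        raise ValueError(f"unknown family {self.family!r}")

    def build(self, n_inputs: int, n_classes: int):
        return build_model(self.network_spec(n_inputs, n_classes), self.training)


def _clamp_gene(value: float, low: float, high: float, integer: bool, odd: bool = False) -> float:
    value = min(max(value, low), high)
    if integer:
        value = int(round(value))
        value = min(max(value, int(low)), int(high))
    if odd and value % 2 == 0:
        value = value + 1 if value + 1 <= high else value - 1
    return value


def _family_bounds(family: str, n_inputs: int | None = None):
    """Structure-gene bounds, with the CNN filter size capped by the input width."""
    bounds = [tuple(b) for b in STRUCTURE_BOUNDS[family]]
    if family == "cnn" and n_inputs is not None:
        low, high, integer = bounds[1]
        cap = min(high, n_inputs if n_inputs % 2 == 1 else n_inputs - 1)
        bounds[1] = (low, cap, integer)
    return bounds


def _repair_structure(genes: np.ndarray, family: str, bounds=None) -> np.ndarray:
    bounds = bounds if bounds is not None else STRUCTURE_BOUNDS[family]
    out = np.array(genes, dtype=float)
    for i in range(out.size):
        low, high, integer = bounds[min(i, len(bounds) - 1)]
        odd = family == "cnn" and i == 1
        if family == "ffnn":
            # widths uncapped during the search: only the floor applies
            out[i] = max(int(round(out[i])), 1)
        else:
            out[i] = _clamp_gene(out[i], low, high, integer, odd)
    return out


def init_structure_population(
    family: str, n: int, rng: np.random.Generator, bounds=None
) -> list[np.ndarray]:
    """Normal initialization centered mid-range with SD = range/6.

    FFNN individuals additionally draw their depth uniformly from {1, 2}.
    """
    if family not in STRUCTURE_BOUNDS:
        raise ValueError(f"unknown family {family!r}")
    bounds = bounds if bounds is not None else STRUCTURE_BOUNDS[family]
    for low, high, _ in bounds:
        if high < low:
            raise ValueError("invalid bounds: high < low")
    population = []
    for _ in range(n):
        if family == "ffnn":
            depth = int(rng.integers(1, 3))
            gene_bounds = [bounds[0]] * depth
        else:
            gene_bounds = bounds
        genes = []
        for i, (low, high, integer) in enumerate(gene_bounds):
            mid = (low + high) / 2.0
            sd = (high - low) / 6.0
            value = mid if sd == 0 else rng.normal(mid, sd)
            odd = family == "cnn" and i == 1
            genes.append(_clamp_gene(value, low, high, integer, odd))
        population.append(np.asarray(genes, dtype=float))
    return population


def single_point_crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Child takes a prefix of one parent and the suffix of the other.

    Length-1 genomes are degenerate: the child copies a uniformly chosen
    parent.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("single-point crossover requires equal lengths")
    if a.size == 1:
        return (a if rng.random() < 0.5 else b).copy()
    cut = int(rng.integers(1, a.size))
    return np.concatenate([a[:cut], b[cut:]])


def gaussian_mutation(
    genes: np.ndarray,
    rng: np.random.Generator,
    sigma: float = 0.1,
    bounds=None,
    family: str | None = None,
) -> np.ndarray:
    """Multiply one uniformly chosen gene by a Normal(1, sigma) draw."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = np.array(genes, dtype=float)
    i = int(rng.integers(out.size))
    out[i] *= rng.normal(1.0, sigma)
    if family is not None:
        out = _repair_structure(out, family, bounds)
    elif bounds is not None:
        low, high, integer = bounds[min(i, len(bounds) - 1)]
        out[i] = _clamp_gene(out[i], low, high, integer)
    return out


def midpoint_crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """FFNN depth-aware crossover: first half of ``a`` + last half of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (1 <= a.size <= 2 and 1 <= b.size <= 2):
        raise ValueError("FFNN genomes have 1 or 2 genes")
    head = a[: int(np.ceil(a.size / 2))]
    tail = b[-int(np.ceil(b.size / 2)) :]
    return np.concatenate([head, tail])[:2]


def ffnn_mutation(
    genes: np.ndarray, rng: np.random.Generator, sigma: float = 0.1
) -> np.ndarray:
    """Gaussian change of one layer width, or of all widths by a shared factor."""
    out = np.array(genes, dtype=float)
    if rng.random() < 0.5:
        i = int(rng.integers(out.size))
        out[i] *= rng.normal(1.0, sigma)
    else:
        out *= rng.normal(1.0, sigma)
    return _repair_structure(out, "ffnn")


# ---------------------------------------------------------------------------
# decoding and the two searches


def decode_structure(family: str, genes: np.ndarray, bounds=None) -> tuple:
    genes = _repair_structure(np.asarray(genes, dtype=float), family, bounds)
    return tuple(int(g) for g in genes)


def _learning_gene_bounds(family: str):
    keys = ["lr", "epochs"] + (["dropout"] if family == "ffnn" else [])
    return keys, [LEARNING_BOUNDS[k] for k in keys]


def decode_learning(family: str, genes: np.ndarray, seed: int = 0) -> TrainingParams:
    keys, bounds = _learning_gene_bounds(family)
    values = {}
    for key, gene, (low, high, integer) in zip(keys, genes, bounds):
        values[key] = _clamp_gene(float(gene), low, high, integer)
    return TrainingParams(
        learning_rate=float(values["lr"]),
        epochs=int(values["epochs"]),
        dropout_rate=float(values.get("dropout", 0.0)),
        seed=seed,
    )


def _structure_fitness_fn(family, X, y, activation, training, config):
    n_classes = len(np.unique(y))

    def fitness(genes):
        structure = decode_structure(family, genes)
        spec = ModelSpec(family, structure, training, activation, seed=config.seed)
        factory = lambda: spec.build(X.shape[1], n_classes)  # noqa: E731
        return _safe_cv_fitness(X, y, factory, config.cv_folds, config.seed, config.cv_repeats)

    return fitness


def optimize_structure(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig | None = None,
    sigma: float = 0.1,
    training: TrainingParams | None = None,
    activation: str | None = None,
) -> tuple[tuple, GAResult]:
    """Step 1: GA over structural genes with baseline training parameters."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or GAConfig(population_size=40, generations=10)
    training = training or BASELINE_TRAINING
    activation = activation or DEFAULT_ACTIVATIONS[family]
    rng = np.random.default_rng(config.seed)
    bounds = _family_bounds(family, X.shape[1])
    initial = init_structure_population(family, config.population_size, rng, bounds=bounds)
    if family == "ffnn":
        crossover, mutate = midpoint_crossover, (
            lambda g, r: ffnn_mutation(g, r, sigma)
        )
    else:
        crossover = single_point_crossover
        mutate = lambda g, r: gaussian_mutation(  # noqa: E731
            g, r, sigma, bounds=bounds, family=family
        )
    result = evolve(
        initial,
        _structure_fitness_fn(family, X, y, activation, training, config),
        crossover=crossover,
        mutate=mutate,
        config=config,
        repair=lambda g, r: _repair_structure(g, family, bounds),
    )
    return decode_structure(family, result.best_individual.genome, bounds), result


def _init_learning_population(family, n, rng):
    keys, bounds = _learning_gene_bounds(family)
    population = []
    for _ in range(n):
        genes = []
        for low, high, integer in bounds:
            mid = (low + high) / 2.0
            sd = (high - low) / 6.0
            genes.append(_clamp_gene(rng.normal(mid, sd), low, high, integer))
        population.append(np.asarray(genes, dtype=float))
    return population


def _learning_mutation(family, genes, rng, sigma):
    keys, bounds = _learning_gene_bounds(family)
    out = np.array(genes, dtype=float)
    if family == "ffnn" and rng.random() < 0.5:
        # dropout-specific Gaussian mutation
        i = keys.index("dropout")
        out[i] = out[i] * rng.normal(1.0, sigma) if out[i] > 0 else rng.normal(0.1, sigma)
    else:
        i = int(rng.integers(out.size))
        out[i] *= rng.normal(1.0, sigma)
    for j, (low, high, integer) in enumerate(bounds):
        out[j] = _clamp_gene(out[j], low, high, integer)
    return out


def optimize_learning(
    family: str,
    structure: tuple,
    X: np.ndarray,
    y: np.ndarray,
    config: GAConfig | None = None,
    sigma: float = 0.1,
    activation: str | None = None,
) -> tuple[TrainingParams, GAResult]:
    """Step 2: GA over learning rate, epochs (and dropout for the FFNN)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or GAConfig(population_size=40, generations=10)
    activation = activation or DEFAULT_ACTIVATIONS[family]
    n_classes = len(np.unique(y))
    rng = np.random.default_rng(config.seed)
    keys, bounds = _learning_gene_bounds(family)

    def repair(genes, r):
        out = np.array(genes, dtype=float)
        for j, (low, high, integer) in enumerate(bounds):
            out[j] = _clamp_gene(out[j], low, high, integer)
        return out

    def fitness(genes):
        params = decode_learning(family, genes, seed=config.seed)
        spec = ModelSpec(family, tuple(structure), params, activation, seed=config.seed)
        factory = lambda: spec.build(X.shape[1], n_classes)  # noqa: E731
        return _safe_cv_fitness(X, y, factory, config.cv_folds, config.seed, config.cv_repeats)

    result = evolve(
        _init_learning_population(family, config.population_size, rng),
        fitness,
        crossover=single_point_crossover,
        mutate=lambda g, r: _learning_mutation(family, g, r, sigma),
        config=config,
        repair=repair,
    )
    params = decode_learning(family, result.best_individual.genome, seed=config.seed)
    return params, result


def two_step_optimize(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    structure_config: GAConfig | None = None,
    learning_config: GAConfig | None = None,
    sigma: float = 0.1,
    activation: str | None = None,
) -> ModelSpec:
    """Run structure search, then learning search with the best structure."""
    structure, s_result = optimize_structure(
        family, X, y, config=structure_config, sigma=sigma, activation=activation
    )
    learning_config = learning_config or structure_config
    params, l_result = optimize_learning(
        family, structure, X, y, config=learning_config, sigma=sigma, activation=activation
    )
    seed = (structure_config or GAConfig()).seed
    return ModelSpec(
        family,
        structure,
        params,
        activation or DEFAULT_ACTIVATIONS[family],
        seed=seed,
        structure_result=s_result,
        learning_result=l_result,
    )


class TwoStepSearch(ClassifierMixin, BaseEstimator):
    """Meta-estimator: two-step GA search, then fit the winning model.

    ``fit`` runs the structure and learning searches on the training data
    and refits the decoded best model; ``predict`` delegates to it.
    """

    def __init__(
        self,
        family: str = "ffnn",
        population_size: int = 40,
        generations: int = 10,
        sigma: float = 0.1,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.family = family
        self.population_size = population_size
        self.generations = generations
        self.sigma = sigma
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        config = GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            seed=self.random_state,
            cv_folds=self.cv,
        )
        self.model_spec_ = two_step_optimize(
            self.family, X, y, structure_config=config, learning_config=config,
            sigma=self.sigma,
        )
        self.classes_ = np.unique(y)
        self.best_estimator_ = self.model_spec_.build(X.shape[1], len(self.classes_))
        self.best_estimator_.fit(X, y)
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)
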