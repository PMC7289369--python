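"""Accuracy and Cohen's Kappa evaluation with repeated-run summaries.

Kappa corrects the observed agreement p0 for the chance agreement pc
obtained from the marginal class frequencies:

    kappa = (p0 - pc) / (1 - pc),  pc = sum_c (row_c / N) * (col_c / N)

Experiments are summarized over repeated trainings (default 15) as
mean +/- SD and best kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

__all__ = [
    "EvalResult",
    "RunSummary",
    "confusion_matrix",
    "cohen_kappa",
    "evaluate_model",
    "repeated_runs",
]


@dataclass
class EvalResult:
    confusion: np.ndarray  # rows = true class
    accuracy: float
    chance_agreement: float
    kappa: float


@dataclass
class RunSummary:
    per_run_kappa: np.ndarray
    mean: float
    sd: float
    best: float

    @classmethod
    def from_series(cls, kappas) -> "RunSummary":
        k = np.asarray(kappas, dtype=float)
        return cls(k, float(k.mean()), float(k.std(ddof=1)) if k.size > 1 else 0.0,
                   float(k.max()))


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    c = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    out = np.zeros((c, c), dtype=int)
    np.add.at(out, (y_true, y_pred), 1)
    return out


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion table."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p0 = np.trace(confusion) / total
    pc = float(np.sum(confusion.sum(axis=1) * confusion.sum(axis=0)) / total**2)
    if pc >= 1.0:
        raise ValueError("degenerate table: chance agreement is 1")
    return float((p0 - pc) / (1.0 - pc))


def evaluate_model(model, X, y) -> EvalResult:
    """Confusion, accuracy, chance agreement, and kappa on a test set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = np.asarray(model.predict(X), dtype=int)
    n_classes = max(len(getattr(model, "classes_", [])), y.max() + 1, pred.max() + 1)
    conf = confusion_matrix(y, pred, n_classes)
    total = conf.sum()
    p0 = float(np.trace(conf) / total)
    pc = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / total**2)
    return EvalResult(conf, p0, pc, cohen_kappa(conf))


def repeated_runs(
    model_factory, X_train, y_train, X_test, y_test,
    n_repetitions: int = 15, base_seed: int = 0,
    on_divergence: str = "raise",
) -> RunSummary:
    """Train and evaluate ``n_repetitions`` times with seeds base..base+n-1.

    ``model_factory`` maps a seed to a fresh unfitted classifier (an
    sklearn estimator is cloned and its ``random_state`` set when the
    factory takes no argument).  A run whose training diverges either
    propagates the error (``on_divergence="raise"``) or is scored kappa 0
    (``"zero"``), the floor for a model with no usable predictions.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if on_divergence not in ("raise", "zero"):
        raise ValueError("on_divergence must be 'raise' or 'zero'")
    kappas = []
    for i in range(n_repetitions):
        seed = base_seed + i
        try:
            model = model_factory(seed)
        except TypeError:
            model = clone(model_factory())
            model.set_params(random_state=seed)
        try:
            model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
            kappas.append(evaluate_model(model, X_test, y_test).kappa)
        except FloatingPointError:
            if on_divergence == "raise":
                raise
            kappas.append(0.0)
    return RunSummary.from_series(kappas)
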