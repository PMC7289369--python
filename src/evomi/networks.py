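"""Shallow neural classifiers for wavelet-variance EEG patterns.

Three families, each deliberately shallow and trained with plain
stochastic gradient descent on the softmax cross-entropy:

* ``FFNNClassifier`` — 1–2 dense hidden layers with dropout (default ELU);
* ``CNN1DClassifier`` — one valid-mode 1-D convolutional layer (true
  convolution, filter flipped) followed by flatten and a dense softmax
  output (default ReLU);
* ``GRUClassifier`` — the feature vector read as a sequence through a
  single GRU layer, classifying from the final hidden state (default ReLU
  on the state before the output layer).

All gradients are computed analytically in numpy; they are checked against
finite differences in the test suite.  The GRU candidate state follows the
convention ``h~ = tanh(Wh x + Uh (r∘h_prev + bh))`` with the bias inside
the recurrent product.

The estimators are sklearn-compatible (``get_params``/``set_params``,
``fit``/``predict``/``predict_proba``, fitted attributes with trailing
underscores) so they compose with pipelines and the GA searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ACTIVATIONS",
    "activation",
    "conv1d_valid",
    "gru_step",
    "CNNSpec",
    "FFNNSpec",
    "RNNSpec",
    "TrainingParams",
    "FFNNClassifier",
    "CNN1DClassifier",
    "GRUClassifier",
    "build_model",
    "train_model",
    "predict",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# activation primitives


def _relu(x):
    return np.maximum(0.0, x)


def _drelu(x):
    return (x > 0).astype(float)


def _leaky_relu(x):
    return np.where(x > 0, x, 0.01 * x)


def _dleaky_relu(x):
    return np.where(x > 0, 1.0, 0.01)


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _delu(x):
    return np.where(x > 0, 1.0, np.exp(x))


def _dtanh(x):
    return 1.0 - np.tanh(x) ** 2


ACTIVATIONS = {
    "tanh": (np.tanh, _dtanh),
    "relu": (_relu, _drelu),
    "leaky_relu": (_leaky_relu, _dleaky_relu),
    "elu": (_elu, _delu),
}


def activation(name: str, x):
    """Evaluate a named activation (tanh, relu, leaky_relu, elu)."""
    if name not in ACTIVATIONS:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")
    return ACTIVATIONS[name][0](np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# structural primitives


def conv1d_valid(signal: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Discrete 1-D convolution restricted to fully-overlapping positions.

    For a filter of odd length ``2k+1`` and an input of length ``n`` the
    output has length ``n - 2k``; element ``i`` is
    ``sum_u filt[u] * signal[i - u]`` over the valid range (the filter is
    flipped, as in true convolution — border positions are discarded).
    """
    signal = np.asarray(signal, dtype=float)
    filt = np.asarray(filt, dtype=float)
    if filt.ndim != 1 or signal.ndim != 1:
        raise ValueError("signal and filter must be 1-D")
    if filt.size % 2 == 0:
        raise ValueError("filter length must be odd")
    if filt.size > signal.size:
        raise ValueError("filter longer than signal")
    return np.convolve(signal, filt, mode="valid")


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, weights: dict) -> np.ndarray:
    """One GRU recurrence step.

    ``weights`` holds Wr, Wz, Wh of shape (H, m), Ur, Uz, Uh of shape
    (H, H) and biases br, bz, bh of shape (H,).  Reset and update gates use
    the logistic sigmoid; the candidate state is
    ``tanh(Wh x + Uh (r∘h_prev + bh))`` and the new state interpolates
    ``h = z∘h_prev + (1−z)∘h~``.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    Wr, Ur, br = weights["Wr"], weights["Ur"], weights["br"]
    Wz, Uz, bz = weights["Wz"], weights["Uz"], weights["bz"]
    Wh, Uh, bh = weights["Wh"], weights["Uh"], weights["bh"]
    if Wr.shape[1] != x_t.shape[-1] or Ur.shape[1] != h_prev.shape[-1]:
        raise ValueError("weight dimensions inconsistent with inputs")
    r = _sigmoid(Wr @ x_t + Ur @ h_prev + br)
    z = _sigmoid(Wz @ x_t + Uz @ h_prev + bz)
    h_cand = np.tanh(Wh @ x_t + Uh @ (r * h_prev + bh))
    return z * h_prev + (1.0 - z) * h_cand


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softmax(logits):
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model specifications


@dataclass
class CNNSpec:
    """One convolutional hidden layer: at most 250 filters of odd size <= 19."""

    n_filters: int
    filter_size: int
    n_inputs: int
    n_classes: int
    activation: str = "relu"

    def __post_init__(self):
        if not (1 <= self.n_filters <= 250):
            raise ValueError("n_filters must be in [1, 250]")
        if not (1 <= self.filter_size <= 19) or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be odd and in [1, 19]")
        if self.filter_size > self.n_inputs:
            raise ValueError("filter longer than input")


@dataclass
class FFNNSpec:
    """One or two dense hidden layers of free width."""

    hidden_widths: tuple
    n_inputs: int
    n_classes: int
    activation: str = "elu"
    dropout_rate: float = 0.0

    def __post_init__(self):
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if not (1 <= len(self.hidden_widths) <= 2):
            raise ValueError("FFNN depth must be 1 or 2 hidden layers")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class RNNSpec:
    """A single GRU layer of at most 60 units."""

    gru_units: int
    n_inputs: int
    n_classes: int
    activation: str = "relu"
    step_size: int = 1

    def __post_init__(self):
        if not (1 <= self.gru_units <= 60):
            raise ValueError("gru_units must be in [1, 60]")
        if self.n_inputs % self.step_size != 0:
            raise ValueError("n_inputs must be divisible by step_size")


@dataclass
class TrainingParams:
    """Learning hyperparameters tuned in the second optimization step."""

    learning_rate: float = 0.1
    epochs: int = 60
    dropout_rate: float = 0.0
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (1 <= self.epochs <= 200):
            raise ValueError("epochs must be in [1, 200]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# estimator base


class _ShallowNetBase(ClassifierMixin, BaseEstimator):
    """Shared SGD training loop on softmax cross-entropy."""

    _max_grad_norm = 5.0  # global-norm gradient clip

    def _init_params(self, n_features, n_classes, rng):  # pragma: no cover
        raise NotImplementedError

    def _forward(self, X, train, rng):  # pragma: no cover
        raise NotImplementedError

    def _backward(self, cache, dlogits):  # pragma: no cover
        raise NotImplementedError

    def _validate_spec(self, n_features):
        pass

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (patterns, features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        self._validate_spec(d)
        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(d, len(self.classes_), rng)
        self.n_features_in_ = d
        self.loss_curve_ = []
        batch = max(1, int(self.batch_size))
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                # overflow in a diverging candidate is expected and surfaces
                # as a non-finite loss below
                with np.errstate(over="ignore", invalid="ignore"):
                    probs, cache = self._forward(X[idx], train=True, rng=rng)
                    onehot = np.eye(len(self.classes_))[y_idx[idx]]
                    eps = 1e-12
                    loss = -np.mean(np.sum(onehot * np.log(probs + eps), axis=1))
                    if not np.isfinite(loss):
                        raise FloatingPointError(
                            f"non-finite training loss ({loss}); try a smaller "
                            f"learning rate (current {self.learning_rate})"
                        )
                    epoch_loss += loss * len(idx)
                    dlogits = (probs - onehot) / len(idx)
                    grads = self._backward(cache, dlogits)
                # global-norm gradient clipping keeps large learning rates
                # stable instead of diverging
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                scale = min(1.0, self._max_grad_norm / norm) if norm > 0 else 1.0
                for key, g in grads.items():
                    self.params_[key] -= self.learning_rate * scale * g
            self.loss_curve_.append(epoch_loss / n)
        self.n_parameters_ = int(sum(p.size for p in self.params_.values()))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        probs, _ = self._forward(X, train=False, rng=None)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# feed-forward network


class FFNNClassifier(_ShallowNetBase):
    """Fully-connected network with 1–2 hidden layers and inverted dropout."""

    def __init__(
        self,
        hidden_widths=(100,),
        activation="elu",
        dropout_rate=0.0,
        learning_rate=0.1,
        epochs=60,
        batch_size=16,
        random_state=None,
    ):
        self.hidden_widths = hidden_widths
        self.activation = activation
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_spec(self, n_features):
        FFNNSpec(
            tuple(self.hidden_widths), n_features, 2,
            activation=self.activation, dropout_rate=self.dropout_rate,
        )

    def _init_params(self, d, c, rng):
        widths = [d, *[int(w) for w in self.hidden_widths], c]
        params = {}
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            params[f"W{i}"] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out))
            params[f"b{i}"] = np.zeros(fan_out)
        return params

    def _forward(self, X, train, rng):
        act, _ = ACTIVATIONS[self.activation]
        n_hidden = len(self.hidden_widths)
        a = X
        pre, acts, masks = [], [X], []
        for i in range(n_hidden):
            z = a @ self.params_[f"W{i}"] + self.params_[f"b{i}"]
            a = act(z)
            if train and self.dropout_rate > 0.0:
                keep = 1.0 - self.dropout_rate
                m = (rng.random(a.shape) < keep) / keep
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            pre.append(z)
            acts.append(a)
        logits = a @ self.params_[f"W{n_hidden}"] + self.params_[f"b{n_hidden}"]
        probs = _softmax(logits)
        return probs, (pre, acts, masks)

    def _backward(self, cache, dlogits):
        pre, acts, masks = cache
        _, dact = ACTIVATIONS[self.activation]
        n_hidden = len(self.hidden_widths)
        grads = {}
        grads[f"W{n_hidden}"] = acts[-1].T @ dlogits
        grads[f"b{n_hidden}"] = dlogits.sum(axis=0)
        da = dlogits @ self.params_[f"W{n_hidden}"].T
        for i in range(n_hidden - 1, -1, -1):
            if masks[i] is not None:
                da = da * masks[i]
            dz = da * dact(pre[i])
            grads[f"W{i}"] = acts[i].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            if i > 0:
                da = dz @ self.params_[f"W{i}"].T
        return grads


# ---------------------------------------------------------------------------
# 1-D convolutional network


class CNN1DClassifier(_ShallowNetBase):
    """Single valid-mode convolutional layer, flatten, dense softmax output."""

    def __init__(
        self,
        n_filters=130,
        filter_size=5,
        activation="relu",
        learning_rate=0.1,
        epochs=60,
        batch_size=16,
        random_state=None,
    ):
        self.n_filters = n_filters
        self.filter_size = filter_size
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_spec(self, n_features):
        CNNSpec(self.n_filters, self.filter_size, n_features, 2, self.activation)

    def _init_params(self, d, c, rng):
        k = self.filter_size
        out_len = d - k + 1
        params = {
            # stored pre-flipped so the forward pass is a plain sliding dot
            # product; the true convolution filters are np.flip of these rows
            "Wc": rng.normal(0.0, 1.0 / np.sqrt(k), (k, self.n_filters)),
            "bc": np.zeros(self.n_filters),
            "Wo": rng.normal(
                0.0, 1.0 / np.sqrt(out_len * self.n_filters),
                (out_len * self.n_filters, c),
            ),
            "bo": np.zeros(c),
        }
        return params

    @property
    def filters_(self):
        """Convolution filters in Eq-style orientation (flipped kernel rows)."""
        check_is_fitted(self, "params_")
        return np.flip(self.params_["Wc"], axis=0).T

    def _forward(self, X, train, rng):
        act, _ = ACTIVATIONS[self.activation]
        windows = sliding_window_view(X, self.filter_size, axis=1)  # (n, L, k)
        H = windows @ self.params_["Wc"] + self.params_["bc"]  # (n, L, F)
        A = act(H)
        flat = A.reshape(X.shape[0], -1)
        logits = flat @ self.params_["Wo"] + self.params_["bo"]
        return _softmax(logits), (windows, H, A.shape)

    def _backward(self, cache, dlogits):
        windows, H, a_shape = cache
        _, dact = ACTIVATIONS[self.activation]
        grads = {}
        flat = ACTIVATIONS[self.activation][0](H).reshape(dlogits.shape[0], -1)
        grads["Wo"] = flat.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dA = (dlogits @ self.params_["Wo"].T).reshape(a_shape)
        dH = dA * dact(H)
        grads["bc"] = dH.sum(axis=(0, 1))
        grads["Wc"] = np.einsum("nlk,nlf->kf", windows, dH)
        return grads


# ---------------------------------------------------------------------------
# gated recurrent network


class GRUClassifier(_ShallowNetBase):
    """Feature vector read as a sequence through one GRU layer.

    The input pattern of ``d`` features becomes ``d / step_size`` time
    steps of ``step_size`` values (default univariate).  Classification is
    a dense softmax layer on the activated final hidden state.
    """

    def __init__(
        self,
        n_units=16,
        activation="relu",
        step_size=1,
        learning_rate=0.1,
        epochs=60,
        batch_size=16,
        random_state=None,
    ):
        self.n_units = n_units
        self.activation = activation
        self.step_size = step_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_spec(self, n_features):
        RNNSpec(self.n_units, n_features, 2, self.activation, self.step_size)

    def _init_params(self, d, c, rng):
        H, m = int(self.n_units), int(self.step_size)
        def w(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape)
        params = {}
        for gate in ("r", "z", "h"):
            params[f"W{gate}"] = w((H, m), m)
            params[f"U{gate}"] = w((H, H), H)
            params[f"b{gate}"] = np.zeros(H)
        params["Wo"] = w((H, c), H)
        params["bo"] = np.zeros(c)
        return params

    def _forward(self, X, train, rng):
        p = self.params_
        act, _ = ACTIVATIONS[self.activation]
        n, d = X.shape
        m = int(self.step_size)
        steps = X.reshape(n, d // m, m)
        h = np.zeros((n, p["Ur"].shape[0]))
        trace = []
        for t in range(steps.shape[1]):
            x = steps[:, t, :]
            r = _sigmoid(x @ p["Wr"].T + h @ p["Ur"].T + p["br"])
            z = _sigmoid(x @ p["Wz"].T + h @ p["Uz"].T + p["bz"])
            q = r * h + p["bh"]
            h_cand = np.tanh(x @ p["Wh"].T + q @ p["Uh"].T)
            h_new = z * h + (1.0 - z) * h_cand
            trace.append((x, h, r, z, q, h_cand))
            h = h_new
        a = act(h)
        logits = a @ p["Wo"] + p["bo"]
        return _softmax(logits), (trace, h, a)

    def _backward(self, cache, dlogits):
        p = self.params_
        trace, h_final, a = cache
        _, dact = ACTIVATIONS[self.activation]
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = a.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = (dlogits @ p["Wo"].T) * dact(h_final)
        for x, h_prev, r, z, q, h_cand in reversed(trace):
            dz = dh * (h_prev - h_cand)
            dh_cand = dh * (1.0 - z)
            dh_prev = dh * z
            dp_ = dh_cand * (1.0 - h_cand**2)
            grads["Wh"] += dp_.T @ x
            grads["Uh"] += dp_.T @ q
            dq = dp_ @ p["Uh"]
            grads["bh"] += dq.sum(axis=0)
            dr = dq * h_prev
            dh_prev += dq * r
            dar = dr * r * (1.0 - r)
            grads["Wr"] += dar.T @ x
            grads["Ur"] += dar.T @ h_prev
            grads["br"] += dar.sum(axis=0)
            dh_prev += dar @ p["Ur"]
            daz = dz * z * (1.0 - z)
            grads["Wz"] += daz.T @ x
            grads["Uz"] += daz.T @ h_prev
            grads["bz"] += daz.sum(axis=0)
            dh_prev += daz @ p["Uz"]
            dh = dh_prev
        return grads


# ---------------------------------------------------------------------------
# factory helpers


def build_model(spec, training: TrainingParams | None = None):
    """Instantiate the classifier a specification describes."""
    training = training or TrainingParams()
    common = dict(
        learning_rate=training.learning_rate,
        epochs=training.epochs,
        batch_size=training.batch_size,
        random_state=training.seed,
    )
    if isinstance(spec, CNNSpec):
        return CNN1DClassifier(
            n_filters=spec.n_filters, filter_size=spec.filter_size,
            activation=spec.activation, **common,
        )
    if isinstance(spec, FFNNSpec):
        dropout = training.dropout_rate if training.dropout_rate else spec.dropout_rate
        return FFNNClassifier(
            hidden_widths=spec.hidden_widths, activation=spec.activation,
            dropout_rate=dropout, **common,
        )
    if isinstance(spec, RNNSpec):
        return GRUClassifier(
            n_units=spec.gru_units, activation=spec.activation,
            step_size=spec.step_size, **common,
        )
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def train_model(model, X, y, params: TrainingParams | None = None):
    """Fit ``model`` (optionally overriding training params); returns it with history."""
    if params is not None:
        model.set_params(
            learning_rate=params.learning_rate,
            epochs=params.epochs,
            batch_size=params.batch_size,
            random_state=params.seed,
        )
        if isinstance(model, FFNNClassifier) and params.dropout_rate:
            model.set_params(dropout_rate=params.dropout_rate)
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model, model.loss_curve_


def predict(model, X):
    """Predicted labels and class probabilities."""
    probs = model.predict_proba(np.asarray(X, dtype=float))
    return model.classes_[np.argmax(probs, axis=1)], probs


def count_parameters(spec) -> int:
    """Closed-form trainable-parameter count for a specification."""
    if isinstance(spec, CNNSpec):
        out_len = spec.n_inputs - spec.filter_size + 1
        conv = spec.n_filters * spec.filter_size + spec.n_filters
        dense = out_len * spec.n_filters * spec.n_classes + spec.n_classes
        return conv + dense
    if isinstance(spec, FFNNSpec):
        widths = [spec.n_inputs, *spec.hidden_widths, spec.n_classes]
        return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
    if isinstance(spec, RNNSpec):
        H, m = spec.gru_units, spec.step_size
        gates = 3 * (H * m + H * H + H)
        return gates + H * spec.n_classes + spec.n_classes
    raise TypeError(f"unknown spec type {type(spec).__name__}")
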