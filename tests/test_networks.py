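"""Network primitives against brute-force oracles, and training behavior."""

import numpy as np
import pytest

from evomi.networks import (
    ACTIVATIONS,
    CNN1DClassifier,
    CNNSpec,
    FFNNClassifier,
    FFNNSpec,
    GRUClassifier,
    RNNSpec,
    TrainingParams,
    activation,
    build_model,
    conv1d_valid,
    count_parameters,
    gru_step,
    predict,
    train_model,
)


def conv_oracle(signal, filt):
    """Direct double-loop convolution over valid positions."""
    k = len(filt) // 2
    n = len(signal)
    out = []
    for center in range(k, n - k):
        acc = 0.0
        for u in range(-k, k + 1):
            acc += filt[u + k] * signal[center - u]
        out.append(acc)
    return np.array(out)


def gru_oracle(x_t, h_prev, w):
    """Scalar-by-scalar evaluation of the gated recurrence."""
    H = len(h_prev)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))  # noqa: E731
    h_t = np.zeros(H)
    r = np.zeros(H)
    z = np.zeros(H)
    for i in range(H):
        ar = sum(w["Wr"][i][j] * x_t[j] for j in range(len(x_t)))
        ar += sum(w["Ur"][i][j] * h_prev[j] for j in range(H)) + w["br"][i]
        r[i] = sig(ar)
        az = sum(w["Wz"][i][j] * x_t[j] for j in range(len(x_t)))
        az += sum(w["Uz"][i][j] * h_prev[j] for j in range(H)) + w["bz"][i]
        z[i] = sig(az)
    for i in range(H):
        p = sum(w["Wh"][i][j] * x_t[j] for j in range(len(x_t)))
        p += sum(w["Uh"][i][j] * (r[j] * h_prev[j] + w["bh"][j]) for j in range(H))
        h_t[i] = z[i] * h_prev[i] + (1 - z[i]) * np.tanh(p)
    return h_t


class TestActivations:
    @pytest.mark.parametrize(
        "name,x,expected",
        [
            ("relu", -2.0, 0.0),
            ("relu", 3.0, 3.0),
            ("leaky_relu", -1.0, -0.01),
            ("leaky_relu", 2.0, 2.0),
            ("elu", 0.0, 0.0),
            ("tanh", 0.0, 0.0),
        ],
    )
    def test_pointwise_values(self, name, x, expected):
        assert activation(name, x) == pytest.approx(expected)

    def test_elu_continuous_at_zero(self):
        eps = 1e-8
        assert activation("elu", -eps) == pytest.approx(0.0, abs=1e-7)
        assert activation("elu", eps) == pytest.approx(0.0, abs=1e-7)

    def test_all_monotone_non_decreasing_on_grid(self):
        grid = np.linspace(-5, 5, 401)
        for name in ACTIVATIONS:
            values = activation(name, grid)
            assert np.all(np.diff(values) >= 0), name

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown activation"):
            activation("swish", 1.0)


class TestConv1d:
    def test_identity_kernel_trims_borders(self, rng):
        x = rng.normal(size=10)
        np.testing.assert_allclose(conv1d_valid(x, [0.0, 1.0, 0.0]), x[1:-1])

    def test_output_length(self, rng):
        out = conv1d_valid(rng.normal(size=3600), rng.normal(size=5))
        assert out.shape == (3596,)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            k = int(rng.choice([1, 3, 5, 7]))
            signal = rng.normal(size=n)
            filt = rng.normal(size=k)
            np.testing.assert_allclose(
                conv1d_valid(signal, filt), conv_oracle(signal, filt), rtol=1e-10
            )

    def test_even_filter_raises(self):
        with pytest.raises(ValueError, match="odd"):
            conv1d_valid(np.zeros(10), np.zeros(4))


class TestGRUStep:
    def test_zero_weights_halve_state(self):
        H = 4
        w = {f"{p}{g}": np.zeros((H, 1) if p == "W" else (H, H))
             for p in ("W", "U") for g in ("r", "z", "h")}
        w.update({f"b{g}": np.zeros(H) for g in ("r", "z", "h")})
        h_prev = np.array([1.0, -2.0, 0.5, 3.0])
        np.testing.assert_allclose(gru_step([0.7], h_prev, w), 0.5 * h_prev)

    def test_zero_everything_stays_zero(self):
        H = 3
        w = {f"{p}{g}": np.zeros((H, 1) if p == "W" else (H, H))
             for p in ("W", "U") for g in ("r", "z", "h")}
        w.update({f"b{g}": np.zeros(H) for g in ("r", "z", "h")})
        np.testing.assert_allclose(gru_step([0.0], np.zeros(H), w), np.zeros(H))

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            H = int(rng.integers(1, 6))
            m = int(rng.integers(1, 4))
            w = {}
            for g in ("r", "z", "h"):
                w[f"W{g}"] = rng.normal(size=(H, m))
                w[f"U{g}"] = rng.normal(size=(H, H))
                w[f"b{g}"] = rng.normal(size=H)
            x = rng.normal(size=m)
            h_prev = rng.normal(size=H)
            np.testing.assert_allclose(
                gru_step(x, h_prev, w), gru_oracle(x, h_prev, w), rtol=1e-9
            )

    def test_dimension_mismatch_raises(self):
        w = {f"{p}{g}": np.zeros((3, 2) if p == "W" else (3, 3))
             for p in ("W", "U") for g in ("r", "z", "h")}
        w.update({f"b{g}": np.zeros(3) for g in ("r", "z", "h")})
        with pytest.raises(ValueError, match="dimension"):
            gru_step(np.zeros(5), np.zeros(3), w)


class TestSpecsAndCounts:
    def test_cnn_flatten_width(self):
        spec = CNNSpec(130, 5, 3600, 3)
        out_len = spec.n_inputs - spec.filter_size + 1
        assert out_len == 3596
        assert spec.n_filters * out_len == 467_480

    def test_parameter_counts_match_fitted_models(self, rng):
        X = rng.random((20, 12))
        y = rng.integers(0, 3, 20)
        cases = [
            (CNNSpec(4, 3, 12, 3), CNN1DClassifier(n_filters=4, filter_size=3, epochs=1)),
            (FFNNSpec((8, 5), 12, 3), FFNNClassifier(hidden_widths=(8, 5), epochs=1)),
            (RNNSpec(6, 12, 3), GRUClassifier(n_units=6, epochs=1)),
        ]
        for spec, model in cases:
            model.set_params(random_state=0).fit(X, y)
            assert model.n_parameters_ == count_parameters(spec)

    def test_cnn_conv_layer_parameter_count(self):
        spec = CNNSpec(7, 5, 30, 2)
        conv_params = spec.n_filters * spec.filter_size + spec.n_filters
        assert conv_params == 42

    @pytest.mark.parametrize(
        "bad",
        [
            lambda: CNNSpec(300, 5, 100, 3),  # too many filters
            lambda: CNNSpec(10, 4, 100, 3),  # even filter size
            lambda: CNNSpec(10, 21, 100, 3),  # filter too large
            lambda: FFNNSpec((10, 10, 10), 100, 3),  # depth 3
            lambda: RNNSpec(61, 100, 3),  # too many units
        ],
    )
    def test_bound_violations_raise(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_build_model_dispatch(self):
        assert isinstance(build_model(CNNSpec(4, 3, 20, 2)), CNN1DClassifier)
        assert isinstance(build_model(FFNNSpec((5,), 20, 2)), FFNNClassifier)
        assert isinstance(build_model(RNNSpec(4, 20, 2)), GRUClassifier)


class TestTraining:
    def test_zero_epochs_leave_parameters_at_init(self, rng):
        X = rng.random((10, 4))
        y = rng.integers(0, 2, 10)
        m = FFNNClassifier(hidden_widths=(3,), epochs=0, random_state=0).fit(X, y)
        fresh = m._init_params(4, 2, np.random.default_rng(0))
        for key in fresh:
            np.testing.assert_array_equal(m.params_[key], fresh[key])

    def test_separable_toy_data_fits_perfectly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-2, 0.3, (25, 2)), rng.normal(2, 0.3, (25, 2))])
        y = np.repeat([0, 1], 25)
        m = FFNNClassifier(hidden_widths=(8,), epochs=200, learning_rate=0.1,
                           random_state=0).fit(X, y)
        assert (m.predict(X) == y).mean() == 1.0

    def test_loss_decreases_over_training(self, rng):
        X = rng.random((40, 6))
        y = rng.integers(0, 3, 40)
        for model in [
            FFNNClassifier(hidden_widths=(10,), epochs=30, random_state=1),
            CNN1DClassifier(n_filters=5, filter_size=3, epochs=30, random_state=1),
            GRUClassifier(n_units=5, epochs=30, random_state=1),
        ]:
            model.fit(X, y)
            assert model.loss_curve_[-1] <= model.loss_curve_[0]

    def test_gradients_match_finite_differences(self, rng):
        X = rng.normal(size=(8, 6))
        y = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        models = [
            FFNNClassifier(hidden_widths=(5, 4), activation="elu", epochs=0, random_state=0),
            CNN1DClassifier(n_filters=3, filter_size=3, epochs=0, random_state=0),
            GRUClassifier(n_units=4, activation="tanh", epochs=0, random_state=0),
            GRUClassifier(n_units=4, step_size=2, epochs=0, random_state=0),
        ]
        onehot = np.eye(3)[y]

        for m in models:
            m.fit(X, y)

            def loss():
                probs, _ = m._forward(X, train=False, rng=None)
                return -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1))

            probs, cache = m._forward(X, train=False, rng=None)
            grads = m._backward(cache, (probs - onehot) / len(y))
            check_rng = np.random.default_rng(0)
            for key, g in grads.items():
                p = m.params_[key]
                for _ in range(min(6, p.size)):
                    idx = np.unravel_index(check_rng.integers(p.size), p.shape)
                    eps = 1e-6
                    orig = p[idx]
                    p[idx] = orig + eps
                    up = loss()
                    p[idx] = orig - eps
                    down = loss()
                    p[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    denom = max(1e-8, abs(numeric) + abs(g[idx]))
                    assert abs(numeric - g[idx]) / denom < 1e-4, (type(m).__name__, key)

    def test_train_model_wrapper_applies_params(self, rng):
        X = rng.random((15, 5))
        y = rng.integers(0, 3, 15)
        model = FFNNClassifier(hidden_widths=(4,))
        params = TrainingParams(learning_rate=0.05, epochs=7, seed=3)
        trained, history = train_model(model, X, y, params)
        assert trained.epochs == 7 and len(history) == 7


class TestPrediction:
    def test_probabilities_sum_to_one(self, rng):
        X = rng.random((12, 5))
        y = rng.integers(0, 3, 12)
        m = GRUClassifier(n_units=3, epochs=5, random_state=0).fit(X, y)
        labels, probs = predict(m, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= set(m.classes_)

    def test_single_class_training_predicts_that_class(self, rng):
        X = rng.random((10, 4))
        y = np.full(10, 2)
        m = FFNNClassifier(hidden_widths=(3,), epochs=10, random_state=0).fit(X, y)
        assert np.all(m.predict(X) == 2)

    def test_inference_is_deterministic(self, rng):
        X = rng.random((10, 4))
        y = rng.integers(0, 2, 10)
        m = FFNNClassifier(hidden_widths=(4,), dropout_rate=0.5, epochs=5,
                           random_state=0).fit(X, y)
        np.testing.assert_array_equal(m.predict_proba(X), m.predict_proba(X))

    def test_width_mismatch_raises(self, rng):
        X = rng.random((10, 4))
        y = rng.integers(0, 2, 10)
        m = FFNNClassifier(hidden_widths=(3,), epochs=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            m.predict(rng.random((3, 5)))
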