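"""Numpy CNN: architecture contract, gradients, training behaviour."""

import numpy as np
import pytest

from pulseco.cnn import (
    CNNRegressor,
    ModelHyperparameters,
    build_cnn,
    parameter_count,
)
from pulseco.exceptions import ConfigurationError, DomainError


class TestArchitecture:
    @pytest.mark.parametrize(
        "n_filters,kernel_size,dense_units",
        [(8, 3, 16), (16, 5, 64), (32, 9, 128)],
    )
    def test_parameter_count_matches_layer_by_layer_sum(
        self, n_filters, kernel_size, dense_units
    ):
        """The trainable-parameter total equals the hand-computed sum:
        conv1 (k·F+F) + bn (2F) + conv2 (k·F²+F) + bn (2F)
        + dense1 (F·⌊(150−2(k−1))/2⌋·U + U) + dense2 (U+1)."""
        h = ModelHyperparameters(
            n_filters=n_filters, kernel_size=kernel_size, dense_units=dense_units
        )
        model = build_cnn(h)
        k, f, u = kernel_size, n_filters, dense_units
        pooled = (150 - 2 * (k - 1)) // 2
        by_hand = (
            (k * f + f) + 2 * f + (k * f * f + f) + 2 * f
            + (f * pooled * u + u) + (u + 1)
        )
        assert model.parameter_count == by_hand == parameter_count(h)

    def test_forward_pass_returns_finite_scalar(self):
        h = ModelHyperparameters(n_filters=8, kernel_size=3, dense_units=16)
        model = build_cnn(h)
        out = model.predict(np.zeros(150))
        assert out.shape == (1,) and np.isfinite(out[0])

    def test_wrong_input_length_rejected(self):
        model = build_cnn(ModelHyperparameters(n_filters=8, kernel_size=3, dense_units=16))
        model.predict(np.zeros(150))  # accepted
        with pytest.raises(DomainError):
            model.predict(np.zeros(149))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelHyperparameters(kernel_size=151)
        with pytest.raises(ConfigurationError):
            ModelHyperparameters(dropout_rate=1.0)
        with pytest.raises(ConfigurationError):
            ModelHyperparameters(learning_rate=0.0)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny
        float64 model (dropout off; BN in training mode)."""
        h = ModelHyperparameters(n_filters=3, kernel_size=3, dense_units=4,
                                 dropout_rate=0.0)
        model = CNNRegressor(h, seed=1, input_length=12)
        for layer in model.layers:
            layer.params = [p.astype(np.float64) for p in layer.params]
            layer.grads = [g.astype(np.float64) for g in layer.grads]
            if hasattr(layer, "running_mean"):
                layer.running_mean = layer.running_mean.astype(np.float64)
                layer.running_var = layer.running_var.astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 12))
        y = rng.normal(size=(5, 1))

        def loss():
            pred = model._forward(model._check_input(x).astype(np.float64), train=True)
            return float(np.mean((pred - y) ** 2))

        pred = model._forward(model._check_input(x).astype(np.float64), train=True)
        model._backward(2.0 * (pred - y) / len(x))
        params = model._get_params()
        grads = [g.copy() for layer in model.layers for g in layer.grads]
        for p, g in zip(params, grads):
            flat, gflat = p.ravel(), g.ravel()
            for j in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[j]
                eps = 1e-6
                flat[j] = orig + eps
                lp = loss()
                flat[j] = orig - eps
                lm = loss()
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(gflat[j], rel=1e-3, abs=1e-7)


class TestTraining:
    def _toy_problem(self, n=200, seed=0):
        """Waveform-like inputs whose amplitude and offset encode the
        target, mimicking the pressure-to-CO regression setting."""
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 150, endpoint=False)
        amp = rng.uniform(0.5, 1.5, n)
        base = rng.uniform(0.0, 1.0, n)
        x = base[:, None] + amp[:, None] * np.sin(2 * np.pi * t)[None, :]
        x = (x + rng.normal(0, 0.01, (n, 150))).astype(np.float32)
        y = 5.0 + 2.0 * amp - base
        return x, y

    def test_constant_target_learned(self):
        x, _ = self._toy_problem(n=120, seed=1)
        y = np.full(120, 6.2)
        h = ModelHyperparameters(n_filters=8, kernel_size=5, dense_units=16,
                                 max_epochs=200, early_stopping_patience=40,
                                 dropout_rate=0.0)
        model = CNNRegressor(h, seed=0).fit(x[:100], y[:100], x[100:], y[100:], seed=1)
        pred = model.predict(x[100:])
        assert np.mean(np.abs(pred - 6.2)) < 0.1
        assert np.max(np.abs(pred - 6.2)) < 0.35

    def test_training_reduces_loss_and_learns_signal(self):
        x, y = self._toy_problem()
        h = ModelHyperparameters(n_filters=8, kernel_size=5, dense_units=32,
                                 max_epochs=80, early_stopping_patience=20,
                                 dropout_rate=0.0, batch_size=32)
        model = CNNRegressor(h, seed=0).fit(x[:160], y[:160], x[160:], y[160:], seed=1)
        assert model.history.train_loss[-1] < model.history.train_loss[0]
        pred = model.predict(x[160:])
        assert np.corrcoef(pred, y[160:])[0, 1] > 0.8

    def test_early_stopping_restores_best_epoch(self):
        x, y = self._toy_problem()
        h = ModelHyperparameters(n_filters=8, kernel_size=5, dense_units=16,
                                 max_epochs=200, early_stopping_patience=5)
        model = CNNRegressor(h, seed=0).fit(x[:160], y[:160], x[160:], y[160:], seed=1)
        assert len(model.history.train_loss) < 200  # stopped early
        best = model.history.best_epoch
        assert model.history.val_loss[best] == pytest.approx(
            min(model.history.val_loss)
        )

    def test_prediction_deterministic(self):
        x, y = self._toy_problem(n=80)
        h = ModelHyperparameters(n_filters=8, kernel_size=3, dense_units=16,
                                 max_epochs=5, early_stopping_patience=5)
        model = CNNRegressor(h, seed=0).fit(x[:60], y[:60], x[60:], y[60:], seed=1)
        assert np.array_equal(model.predict(x), model.predict(x))

    def test_identical_seeds_identical_models(self):
        x, y = self._toy_problem(n=80)
        h = ModelHyperparameters(n_filters=8, kernel_size=3, dense_units=16,
                                 max_epochs=5, early_stopping_patience=5)
        a = CNNRegressor(h, seed=3).fit(x[:60], y[:60], x[60:], y[60:], seed=4)
        b = CNNRegressor(h, seed=3).fit(x[:60], y[:60], x[60:], y[60:], seed=4)
        assert np.array_equal(a.predict(x), b.predict(x))
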