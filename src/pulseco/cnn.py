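"""A compact 1D convolutional regressor, implemented on numpy.

The architecture maps a 150-point single-cycle pressure vector to one
scalar (cardiac output, L/min):

    conv(n_filters, kernel) → batch-norm → ReLU
    → conv(n_filters, kernel) → batch-norm → ReLU
    → max-pool(2) → dropout → flatten
    → dense(dense_units, ReLU) → dense(1, linear)

Training minimizes mean squared error with Adam; early stopping
monitors the validation loss and restores the best-epoch weights.
All convolutions are stride-1 "valid"; forward/backward passes are
vectorized (im2col via stride tricks) so training stays fast on a
single CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, DomainError, TrainingError
from .preprocessing import VECTOR_LENGTH

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelHyperparameters:
    """Tunable hyperparameters of the convolutional regressor."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    n_filters: int = 16
    kernel_size: int = 9
    dropout_rate: float = 0.05
    dense_units: int = 64
    max_epochs: int = 300
    early_stopping_patience: int = 40

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.n_filters,
               self.kernel_size, self.dense_units, self.max_epochs,
               self.early_stopping_patience) <= 0:
            raise ConfigurationError("hyperparameters must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.kernel_size > VECTOR_LENGTH:
            raise ConfigurationError(
                f"kernel_size must not exceed the input length {VECTOR_LENGTH}"
            )


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(_Layer):
    """Stride-1 valid cross-correlation; x is (batch, channels, length)."""

    def __init__(self, in_channels: int, n_filters: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * kernel_size))  # He init
        w = rng.normal(0.0, scale, (n_filters, in_channels, kernel_size))
        self.params = [w.astype(_DTYPE), np.zeros(n_filters, dtype=_DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        if x.shape[2] < self.k:
            raise DomainError("input shorter than kernel")
        self._win = sliding_window_view(x, self.k, axis=2)  # (B, C, L', K)
        w, b = self.params
        return np.einsum("bclk,fck->bfl", self._win, w, optimize=True) + b[None, :, None]

    def backward(self, dy):
        w, _ = self.params
        self.grads[0][...] = np.einsum("bclk,bfl->fck", self._win, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        pad = self.k - 1
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad)))
        dwin = sliding_window_view(dyp, self.k, axis=2)  # (B, F, L, K)
        return np.einsum("bflk,fck->bcl", dwin, w[:, :, ::-1], optimize=True)


class BatchNorm1D(_Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = [np.ones(n_channels, dtype=_DTYPE), np.zeros(n_channels, dtype=_DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(n_channels, dtype=_DTYPE)
        self.running_var = np.ones(n_channels, dtype=_DTYPE)

    def forward(self, x, train):
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._xhat = (x - mean[None, :, None]) / np.sqrt(var + self.eps)[None, :, None]
            self._std = np.sqrt(var + self.eps)
            return gamma[None, :, None] * self._xhat + beta[None, :, None]
        xhat = (x - self.running_mean[None, :, None]) / np.sqrt(
            self.running_var + self.eps
        )[None, :, None]
        return gamma[None, :, None] * xhat + beta[None, :, None]

    def backward(self, dy):
        gamma, _ = self.params
        xhat, std = self._xhat, self._std
        m = dy.shape[0] * dy.shape[2]
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dxhat = dy * gamma[None, :, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        )
        return term / std[None, :, None]


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(_Layer):
    """Non-overlapping pooling of size 2 (trailing odd sample dropped)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train):
        b, c, l = x.shape
        lp = l // self.size
        xr = x[:, :, : lp * self.size].reshape(b, c, lp, self.size)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, l = self._in_shape
        lp = l // self.size
        dx = np.zeros((b, c, lp, self.size), dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros(self._in_shape, dtype=dy.dtype)
        out[:, :, : lp * self.size] = dx.reshape(b, c, lp * self.size)
        return out


class Dropout(_Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params = [w.astype(_DTYPE), np.zeros(n_out, dtype=_DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def parameter_count(h: ModelHyperparameters, input_length: int = VECTOR_LENGTH) -> int:
    """Trainable parameter count as a closed-form function of ``h``."""
    k, f, u = h.kernel_size, h.n_filters, h.dense_units
    l1 = input_length - k + 1
    l2 = l1 - k + 1
    lp = l2 // 2
    conv1 = k * f + f
    conv2 = k * f * f + f
    bn = 2 * f + 2 * f
    dense1 = f * lp * u + u
    dense2 = u + 1
    return conv1 + conv2 + bn + dense1 + dense2


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


class CNNRegressor:
    """1D CNN regressor; build with :func:`build_cnn` or directly."""

    def __init__(self, h: ModelHyperparameters, seed: int = 0,
                 input_length: int = VECTOR_LENGTH) -> None:
        if h.kernel_size > input_length:
            raise ConfigurationError("kernel larger than input")
        self.h = h
        self.input_length = input_length
        rng = np.random.default_rng(seed)
        f, k = h.n_filters, h.kernel_size
        l2 = input_length - 2 * (k - 1)
        if l2 < 2:
            raise ConfigurationError("kernel too large for two valid conv layers")
        lp = l2 // 2
        self.layers: list[_Layer] = [
            Conv1D(1, f, k, rng),
            BatchNorm1D(f),
            ReLU(),
            Conv1D(f, f, k, rng),
            BatchNorm1D(f),
            ReLU(),
            MaxPool1D(2),
            Dropout(h.dropout_rate, rng),
            Flatten(),
            Dense(f * lp, h.dense_units, rng),
            ReLU(),
            Dense(h.dense_units, 1, rng),
        ]
        self.history = TrainingHistory()
        self.trained = False
        self.condition_tag: str | None = None

    # -- plumbing ----------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params))

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != self.input_length:
            raise DomainError(
                f"model input must have length {self.input_length}, got {x.shape}"
            )
        return x[:, None, :]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def _get_params(self):
        return [p for layer in self.layers for p in layer.params]

    def _snapshot(self):
        state = [copy.deepcopy(layer.params) for layer in self.layers]
        bn = [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in self.layers
            if isinstance(layer, BatchNorm1D)
        ]
        return state, bn

    def _restore(self, snap) -> None:
        state, bn = snap
        for layer, params in zip(self.layers, state):
            layer.params = copy.deepcopy(params)
        it = iter(bn)
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean, layer.running_var = next(it)
                layer.running_mean = layer.running_mean.copy()
                layer.running_var = layer.running_var.copy()

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        seed: int = 0,
    ) -> "CNNRegressor":
        """Train with Adam + MSE and patience-based early stopping."""
        h = self.h
        xt = self._check_input(x_train)
        yt = np.asarray(y_train, dtype=_DTYPE).reshape(-1, 1)
        xv = self._check_input(x_val) if len(x_val) else None
        yv = np.asarray(y_val, dtype=_DTYPE).reshape(-1, 1) if len(x_val) else None
        rng = np.random.default_rng(seed)
        params = self._get_params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_snap = self._snapshot()
        patience_left = h.early_stopping_patience
        lr = h.learning_rate
        plateau_patience = max(3, h.early_stopping_patience // 3)
        plateau_left = plateau_patience
        n = xt.shape[0]
        for epoch in range(h.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, h.batch_size):
                idx = order[start : start + h.batch_size]
                xb, yb = xt[idx], yt[idx]
                pred = self._forward(xb, train=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                epoch_loss += loss * len(idx)
                self._backward(2.0 * err.astype(_DTYPE) / len(idx))
                step += 1
                grads = [g for layer in self.layers for g in layer.grads]
                lr_t = lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise TrainingError(
                    f"training diverged at epoch {epoch}: loss={epoch_loss}",
                )
            self.history.train_loss.append(epoch_loss)
            if xv is not None:
                val_pred = self._forward(xv, train=False)
                val_loss = float(np.mean((val_pred - yv) ** 2))
                self.history.val_loss.append(val_loss)
                if val_loss < best_val - 1e-7:
                    best_val = val_loss
                    best_snap = self._snapshot()
                    self.history.best_epoch = epoch
                    patience_left = h.early_stopping_patience
                    plateau_left = plateau_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
                    plateau_left -= 1
                    if plateau_left <= 0:  # reduce-on-plateau schedule
                        lr = max(lr * 0.5, 1e-5)
                        plateau_left = plateau_patience
        if xv is not None:
            self._restore(best_snap)
        self.trained = True
        return self

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Deterministic forward pass (eval mode, running BN statistics)."""
        xb = self._check_input(x)
        out = [
            self._forward(xb[i : i + batch_size], train=False)
            for i in range(0, xb.shape[0], batch_size)
        ]
        return np.concatenate(out).ravel().astype(float)


def build_cnn(h: ModelHyperparameters, seed: int = 0) -> CNNRegressor:
    """Construct an untrained regressor for 150-point inputs."""
    return CNNRegressor(h, seed=seed)
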