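"""Minimal feed-forward / 1-D convolutional network framework in numpy.

Implements exactly the layer types the three network classifiers need —
Dense, Conv1D (valid padding, stride 1), Dropout, MaxPool1D, Flatten — with
Glorot-uniform initialisation, Adam and plain full-batch gradient descent
optimisers, and binary cross-entropy loss on a single sigmoid output.
Everything is seeded: initialisation, batch shuffling and dropout masks all
draw from one generator, so training is reproducible bit-for-bit.

Shapes follow the keras convention: Dense consumes ``(batch, features)``,
Conv1D/MaxPool1D consume ``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "Dropout",
    "MaxPool1D",
    "Flatten",
    "Sequential",
]

_ACTS = {
    "linear": (lambda z: z, lambda z, a: np.ones_like(a)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z, a: a * (1.0 - a),
    ),
}


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(_Layer):
    def __init__(self, units: int, activation: str = "linear") -> None:
        super().__init__()
        self.units = units
        self.act, self.act_grad = _ACTS[activation]

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        self.w = _glorot(rng, (fan_in, self.units), fan_in, self.units)
        self.b = np.zeros(self.units)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, training):
        self._x = x
        self._z = x @ self.w + self.b
        self._a = self.act(self._z)
        return self._a

    def backward(self, grad):
        dz = grad * self.act_grad(self._z, self._a)
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.w.T


class Conv1D(_Layer):
    """Valid-padding, stride-1 temporal convolution."""

    def __init__(self, filters: int, kernel_size: int, activation: str = "linear"):
        super().__init__()
        self.filters = filters
        self.kernel_size = kernel_size
        self.act, self.act_grad = _ACTS[activation]

    def build(self, input_shape, rng):
        length, channels = input_shape
        k = self.kernel_size
        fan_in, fan_out = k * channels, k * self.filters
        self.w = _glorot(rng, (k, channels, self.filters), fan_in, fan_out)
        self.b = np.zeros(self.filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._out_len = length - k + 1
        return (self._out_len, self.filters)

    def forward(self, x, training):
        self._x = x
        out = np.zeros((x.shape[0], self._out_len, self.filters))
        for dk in range(self.kernel_size):
            out += x[:, dk : dk + self._out_len, :] @ self.w[dk]
        out += self.b
        self._z = out
        self._a = self.act(out)
        return self._a

    def backward(self, grad):
        dz = grad * self.act_grad(self._z, self._a)
        dx = np.zeros_like(self._x)
        for dk in range(self.kernel_size):
            xs = self._x[:, dk : dk + self._out_len, :]
            self.grads[0][dk] = np.einsum("blc,blf->cf", xs, dz)
            dx[:, dk : dk + self._out_len, :] += dz @ self.w[dk].T
        self.grads[1][...] = dz.sum(axis=(0, 1))
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def build(self, input_shape, rng):
        self._rng = rng
        return input_shape

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool1D(_Layer):
    """Non-overlapping temporal max pooling (stride = pool size)."""

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        self.pool_size = pool_size

    def build(self, input_shape, rng):
        length, channels = input_shape
        self._out_len = length // self.pool_size
        return (self._out_len, channels)

    def forward(self, x, training):
        p = self.pool_size
        trimmed = x[:, : self._out_len * p, :]
        windows = trimmed.reshape(x.shape[0], self._out_len, p, -1)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, grad):
        b, L, c = grad.shape
        dx = np.zeros(self._in_shape)
        bi, li, ci = np.ogrid[:b, :L, :c]
        dx[bi, li * self.pool_size + self._argmax, ci] = grad
        return dx


class Flatten(_Layer):
    def build(self, input_shape, rng):
        self._in_shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._batch = x.shape[0]
        return x.reshape(self._batch, -1)

    def backward(self, grad):
        return grad.reshape((self._batch, *self._in_shape))


class Sequential:
    """A seeded stack of layers trained with binary cross-entropy.

    ``batch_size=None`` trains full-batch (plain gradient descent when
    ``optimizer='gd'``), otherwise shuffled mini-batches with Adam.
    """

    def __init__(
        self,
        layers: list[_Layer],
        input_shape: tuple,
        *,
        learning_rate: float = 0.001,
        optimizer: str = "adam",
        seed: int = 0,
    ) -> None:
        self.layers = layers
        self.input_shape = input_shape
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.rng = np.random.default_rng(seed)
        shape = input_shape
        for layer in layers:
            shape = layer.build(shape, self.rng)
        if shape != (1,):
            raise ValueError(f"network must end in a single output unit, got {shape}")
        if optimizer == "adam":
            self._m = [np.zeros_like(p) for l in layers for p in l.params]
            self._v = [np.zeros_like(p) for l in layers for p in l.params]
            self._t = 0
        elif optimizer != "gd":
            raise ValueError("optimizer must be 'adam' or 'gd'")

    def _params_grads(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def _step(self) -> None:
        lr = self.learning_rate
        if self.optimizer == "gd":
            for p, g in self._params_grads():
                p -= lr * g
            return
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-7
        for i, (p, g) in enumerate(self._params_grads()):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self._t)
            vhat = self._v[i] / (1 - b2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 100,
        batch_size: int | None = 32,
    ) -> "Sequential":
        x = np.asarray(x, dtype=np.float64).reshape(len(x), *self.input_shape)
        y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
        n = len(x)
        bs = n if batch_size is None else min(batch_size, n)
        for _ in range(epochs):
            order = self.rng.permutation(n) if batch_size is not None else np.arange(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                prob = self.forward(x[idx], training=True)
                prob = np.clip(prob, 1e-12, 1 - 1e-12)
                # d(BCE)/d(prob), mean over the batch
                grad = (prob - y[idx]) / (prob * (1 - prob)) / len(idx)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._step()
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if len(x) == 0:
            return np.zeros(0)
        return self.forward(x.reshape(len(x), *self.input_shape)).ravel()

    def count_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)
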