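"""A small, deterministic 1-D convolutional network engine in numpy.

Implements exactly the pieces the fall-detection architectures need:

* ``conv1d`` — valid (no padding), stride 1, ReLU, optional L2 weight penalty
* ``maxpool`` — non-overlapping, trailing remainder dropped
* ``dropout`` — inverted dropout, active only during training
* ``flatten`` / ``dense`` — fully-connected layers, ReLU or linear
* softmax + log-cosh loss, and SGD with Nesterov momentum and per-update
  learning-rate decay ``lr_t = lr₀ / (1 + decay · t)``

Everything is seeded: weight initialization (Glorot uniform), batch
shuffling and dropout masks all draw from generators handed in by the
caller, so two runs with the same seed produce identical loss histories.

Arrays flow through layers as ``(N, L, C)`` batches (windows × time ×
channels); dense layers see ``(N, features)``.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for overflow safety."""
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def logcosh(r: np.ndarray) -> np.ndarray:
    """Elementwise log(cosh(r)), stable for large |r|.

    Uses log(cosh(r)) = |r| + log(1 + e^{-2|r|}) - log(2), which never
    overflows and agrees with the naive form to machine precision.
    """
    a = np.abs(r)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: trainable parameters live in ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> float:
        """Regularization contribution to the loss."""
        return 0.0


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1, ReLU activation.

    Weights have shape (kernel·in_channels, filters); the L2 penalty
    ``l2 · Σw²`` applies to the kernel weights only, not the bias.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 l2: float = 0.0) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.l2 = l2

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.in_channels
        fan_out = self.kernel * self.filters
        self.params["w"] = glorot_uniform(
            rng, (self.kernel * self.in_channels, self.filters), fan_in, fan_out)
        self.params["b"] = np.zeros(self.filters)

    def forward(self, x, training=False, rng=None):
        # (N, L, C) -> patches (N, Lout, kernel, C) -> (N·Lout, kernel·C)
        n, length, c = x.shape
        lout = length - self.kernel + 1
        if lout < 1:
            raise ValueError(
                f"conv1d kernel {self.kernel} does not fit input length {length}")
        windows = np.lib.stride_tricks.sliding_window_view(
            x, self.kernel, axis=1)            # (N, Lout, C, kernel)
        patches = windows.transpose(0, 1, 3, 2).reshape(n * lout, -1)
        z = patches @ self.params["w"] + self.params["b"]
        self._patches = patches
        self._mask = z > 0
        self._in_shape = (n, length, c)
        return relu(z).reshape(n, lout, self.filters)

    def backward(self, dy):
        n, length, c = self._in_shape
        lout = length - self.kernel + 1
        dz = dy.reshape(n * lout, self.filters) * self._mask
        self.grads["w"] = self._patches.T @ dz + 2.0 * self.l2 * self.params["w"]
        self.grads["b"] = dz.sum(axis=0)
        dpatches = (dz @ self.params["w"].T).reshape(n, lout, self.kernel, c)
        dx = np.zeros((n, length, c))
        for k in range(self.kernel):
            dx[:, k:k + lout, :] += dpatches[:, :, k, :]
        return dx

    def penalty(self) -> float:
        return self.l2 * float(np.sum(self.params["w"] ** 2))


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        n, length, c = x.shape
        lout = length // self.pool
        if lout < 1:
            raise ValueError(
                f"maxpool size {self.pool} does not fit input length {length}")
        trimmed = x[:, :lout * self.pool, :].reshape(n, lout, self.pool, c)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = (n, length, c)
        return trimmed.max(axis=2)

    def backward(self, dy):
        n, length, c = self._in_shape
        lout = length // self.pool
        dx = np.zeros((n, lout, self.pool, c))
        idx_n, idx_l, idx_c = np.ogrid[:n, :lout, :c]
        dx[idx_n, idx_l, self._argmax, idx_c] = dy
        dx = dx.reshape(n, lout * self.pool, c)
        if lout * self.pool < length:
            dx = np.pad(dx, ((0, 0), (0, length - lout * self.pool), (0, 0)))
        return dx


class Dropout(Layer):
    """Inverted dropout: scales kept units by 1/(1−rate) during training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully-connected layer, ReLU or linear activation."""

    def __init__(self, in_features: int, units: int,
                 activation: str = "relu") -> None:
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_features = in_features
        self.units = units
        self.activation = activation

    def initialize(self, rng: np.random.Generator) -> None:
        self.params["w"] = glorot_uniform(
            rng, (self.in_features, self.units), self.in_features, self.units)
        self.params["b"] = np.zeros(self.units)

    def forward(self, x, training=False, rng=None):
        z = x @ self.params["w"] + self.params["b"]
        self._x = x
        if self.activation == "relu":
            self._mask = z > 0
            return relu(z)
        self._mask = None
        return z

    def backward(self, dy):
        dz = dy * self._mask if self._mask is not None else dy
        self.grads["w"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["w"].T


class Network:
    """An ordered layer pipeline with a shared parameter view."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.initialize(rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"layer{i}.{name}": layer.params[name]
                for i, layer in enumerate(self.layers)
                for name in layer.params}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(weights[f"layer{i}.{name}"],
                                                dtype=float)


def softmax_logcosh_loss(logits: np.ndarray,
                         one_hot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean log-cosh between softmax(logits) and one-hot targets.

    Returns (loss, dL/dlogits).  The gradient chains d logcosh = tanh(r)
    through the softmax Jacobian.
    """
    p = softmax(logits)
    r = p - one_hot
    loss = float(np.mean(logcosh(r)))
    dp = np.tanh(r) / r.size
    # softmax Jacobian: dz = p ⊙ (dp − ⟨dp, p⟩)
    dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
    return loss, dz


class SGD:
    """Stochastic gradient descent with Nesterov momentum and decay.

    Uses the classic time-based decay formulation: at update t (0-based),
    ``lr_t = lr / (1 + decay·t)``; ``v ← μ·v − lr_t·g``; the applied step is
    ``μ·v − lr_t·g`` with Nesterov, else ``v``.
    """

    def __init__(self, learning_rate: float, momentum: float = 0.0,
                 decay: float = 0.0, nesterov: bool = False) -> None:
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.decay = decay
        self.nesterov = nesterov
        self.iterations = 0
        self._velocity: dict[int, np.ndarray] = {}

    def step(self, network: Network) -> None:
        lr = self.learning_rate / (1.0 + self.decay * self.iterations)
        for slot, (layer, name) in enumerate(network.parameters()):
            g = layer.grads[name]
            v = self._velocity.get(slot)
            if v is None:
                v = np.zeros_like(g)
            v = self.momentum * v - lr * g
            self._velocity[slot] = v
            if self.nesterov:
                layer.params[name] = layer.params[name] + self.momentum * v - lr * g
            else:
                layer.params[name] = layer.params[name] + v
        self.iterations += 1
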