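"""Minimal numpy layer library with manual backpropagation.

Implements exactly the layer zoo the package's two small networks need:
dense, 1-D convolution with "same" padding, LeakyReLU, max-pooling,
flatten, reshape, dropout, sigmoid/tanh activations, and a bidirectional
LSTM with sum merge.  Conventions (gate order, padding arithmetic, default
initializers, parameter counting) follow the common Keras ones so that
layer parameter counts match the published architecture tables this
package reproduces.

All arrays are float32; sequences are batch-major ``(B, T, C)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    return q[:shape[0], :shape[1]].astype(DTYPE)


class Layer:
    """Base layer: parameters and their gradients live in parallel lists."""

    name = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, init_std: float | None = None,
                 name: str = "dense") -> None:
        super().__init__()
        self.name = name
        if init_std is not None:
            W = (rng.standard_normal((in_features, out_features)) * init_std
                 ).astype(DTYPE)
        else:
            W = glorot_uniform(rng, (in_features, out_features),
                               in_features, out_features)
        b = np.zeros(out_features, dtype=DTYPE)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        W, _ = self.params
        x = self._x
        self.grads[0] += np.tensordot(x, dy, axes=(range(x.ndim - 1),
                                                   range(dy.ndim - 1))).astype(DTYPE)
        self.grads[1] += dy.reshape(-1, dy.shape[-1]).sum(axis=0).astype(DTYPE)
        return dy @ W.T


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" padding (pad K//2-1 left for even K)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv1d") -> None:
        super().__init__()
        self.name = name
        self.K = kernel_size
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        W = glorot_uniform(rng, (kernel_size, in_channels, filters),
                           fan_in, fan_out)
        b = np.zeros(filters, dtype=DTYPE)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size - 1 - self.pad_left

    def _im2col(self, xp: np.ndarray, T: int) -> np.ndarray:
        B, _, C = xp.shape
        s = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp, (B, T, self.K, C), (s[0], s[1], s[1], s[2]), writeable=False)

    def forward(self, x, training=False):
        B, T, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        cols = self._im2col(xp, T)
        self._cols, self._in_shape = cols, x.shape
        return np.tensordot(cols, self.params[0],
                            axes=([2, 3], [0, 1])) + self.params[1]

    def backward(self, dy):
        W, _ = self.params
        B, T, C = self._in_shape
        self.grads[0] += np.tensordot(self._cols, dy,
                                      axes=([0, 1], [0, 1])).astype(DTYPE)
        self.grads[1] += dy.sum(axis=(0, 1)).astype(DTYPE)
        dxp = np.zeros((B, T + self.K - 1, C), dtype=DTYPE)
        for k in range(self.K):
            dxp[:, k:k + T, :] += dy @ W[k].T
        return dxp[:, self.pad_left:self.pad_left + T, :]


class LeakyReLU(Layer):
    name = "leaky_relu"

    def __init__(self, alpha: float = 0.3) -> None:  # Keras default slope
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool1D(Layer):
    """Pool/stride 2, valid semantics: a trailing odd sample is dropped."""

    name = "max_pooling1d"

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, T, C = x.shape
        To = T // self.pool
        xv = x[:, :To * self.pool, :].reshape(B, To, self.pool, C)
        self._arg = xv.argmax(axis=2)
        self._in_shape = x.shape
        return xv.max(axis=2)

    def backward(self, dy):
        B, T, C = self._in_shape
        To = dy.shape[1]
        dx = np.zeros((B, To, self.pool, C), dtype=DTYPE)
        b, t, c = np.ogrid[:B, :To, :C]
        dx[b, t, self._arg, c] = dy
        dx = dx.reshape(B, To * self.pool, C)
        if To * self.pool < T:
            dx = np.pad(dx, ((0, 0), (0, T - To * self.pool), (0, 0)))
        return dx


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    name = "reshape"

    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = target

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sigmoid(Layer):
    name = "sigmoid"

    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    name = "tanh"

    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single-direction LSTM returning the full sequence (B, T, H).

    Gate order i, f, g, o; kernel ``W (C, 4H)``, recurrent ``U (H, 4H)``,
    bias ``(4H,)`` with the forget gate initialized to 1.
    """

    name = "lstm"

    def __init__(self, in_features: int, hidden: int,
                 rng: np.random.Generator, backwards: bool = False) -> None:
        super().__init__()
        self.H = hidden
        self.backwards = backwards
        W = glorot_uniform(rng, (in_features, 4 * hidden), in_features, 4 * hidden)
        U = orthogonal(rng, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.params = [W, U, b]
        self.grads = [np.zeros_like(W), np.zeros_like(U), np.zeros_like(b)]

    def forward(self, x, training=False):
        if self.backwards:
            x = x[:, ::-1, :]
        W, U, b = self.params
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        xW = x @ W + b  # precompute the input contribution for every step
        self._cache = []
        out = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            z = xW[:, t, :] + h @ U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t, :] = h
        self._x = x
        return out[:, ::-1, :] if self.backwards else out

    def backward(self, dy):
        if self.backwards:
            dy = dy[:, ::-1, :]
        W, U, b = self.params
        x = self._x
        B, T, C = x.shape
        H = self.H
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dy[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads[0] += dW
        self.grads[1] += dU
        self.grads[2] += db
        return dx[:, ::-1, :] if self.backwards else dx


class BiLSTM(Layer):
    """Bidirectional LSTM with *sum* merge of the two directions."""

    name = "bidirectional"

    def __init__(self, in_features: int, hidden: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTM(in_features, hidden, rng, backwards=False)
        self.bwd = LSTM(in_features, hidden, rng, backwards=True)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, training=False):
        return self.fwd.forward(x, training) + self.bwd.forward(x, training)

    def backward(self, dy):
        return self.fwd.backward(dy) + self.bwd.backward(dy)


class Sequential:
    """A plain layer stack with reverse-order backprop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def parameter_report(self) -> list[dict]:
        return [{"layer": layer.name, "params": layer.param_count}
                for layer in self.layers]


class Adam:
    """Adam with a mutable learning rate (for step-decay schedules)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray,
                         eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean BCE on probabilities and its gradient w.r.t. ``p``."""
    p = np.clip(p, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    dp = ((p - y) / (p * (1.0 - p))) / p.size
    return loss, dp.astype(DTYPE)
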