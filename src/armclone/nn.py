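"""Minimal NumPy neural-network layers with explicit backpropagation.

These primitives back both the soft actor-critic networks (MLPs) and the
1-D-conv + LSTM regressor.  Every layer caches what its backward pass
needs; ``backward`` consumes the gradient of the loss with respect to
the layer output and returns the gradient with respect to its input,
accumulating parameter gradients in ``grads``.

All computations are float64 and deterministic given the RNG used for
initialization and the order of calls; gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Relu", "Conv1D", "LSTM", "MLP", "Adam", "soft_update"]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic


class Layer:
    """Base: parameters and matching gradient buffers as flat lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def zero_grads(self):
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads[0] += x2.T @ dy2
        self.grads[1] += dy2.sum(axis=0)
        return dy @ self.w.T


class Relu(Layer):
    params: list = []
    grads: list = []

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Conv1D(Layer):
    """Temporal convolution, valid padding, stride 1.

    Input (B, T, C_in) -> output (B, T - k + 1, filters).
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng):
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.w = rng.normal(0.0, scale, size=(kernel * c_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _unfold(self, x):
        b, t, c = x.shape
        k = self.kernel
        to = t - k + 1
        # (B, T_out, k*C) sliding windows
        idx = np.arange(to)[:, None] + np.arange(k)[None, :]
        return x[:, idx, :].reshape(b, to, k * c)

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = self._unfold(x)
        return self._cols @ self.w + self.b

    def backward(self, dy):
        b, to, f = dy.shape
        k = self.kernel
        c = self._x_shape[2]
        cols2 = self._cols.reshape(-1, k * c)
        dy2 = dy.reshape(-1, f)
        self.grads[0] += cols2.T @ dy2
        self.grads[1] += dy2.sum(axis=0)
        dcols = (dy @ self.w.T).reshape(b, to, k, c)
        dx = np.zeros(self._x_shape)
        for j in range(k):
            dx[:, j : j + to, :] += dcols[:, :, j, :]
        return dx


class LSTM(Layer):
    """Single LSTM layer over a full sequence (B, T, C) -> (B, T, H)."""

    def __init__(self, c_in: int, hidden: int, rng):
        self.h = hidden
        scale = np.sqrt(1.0 / (c_in + hidden))
        self.wx = rng.normal(0.0, scale, size=(c_in, 4 * hidden))
        self.wh = rng.normal(0.0, scale, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        b, t, _ = x.shape
        h = self.h
        self._x = x
        self._cache = []
        hs = np.zeros((b, t, h))
        h_prev = np.zeros((b, h))
        c_prev = np.zeros((b, h))
        for k in range(t):
            z = x[:, k, :] @ self.wx + h_prev @ self.wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            self._cache.append((h_prev, c_prev, i, f, g, o, tc))
            hs[:, k, :] = h_new
            h_prev, c_prev = h_new, c
        return hs

    def backward(self, dhs):
        x = self._x
        b, t, _ = x.shape
        h = self.h
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        dwx, dwh, db = self.grads
        for k in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[k]
            dh = dhs[:, k, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dwx += x[:, k, :].T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, k, :] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
        return dx


class MLP(Layer):
    """Fully connected ReLU network with a linear output layer."""

    def __init__(self, sizes: tuple[int, ...], rng):
        self.layers: list[Layer] = []
        for k in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[k], sizes[k + 1], rng))
            if k < len(sizes) - 2:
                self.layers.append(Relu())
        self.params = [p for lay in self.layers for p in lay.params]
        self.grads = [g for lay in self.layers for g in lay.grads]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def soft_update(target: Layer, source: Layer, tau: float):
    """Polyak-average source parameters into the target network."""
    for pt, ps in zip(target.params, source.params):
        pt *= 1.0 - tau
        pt += tau * ps
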