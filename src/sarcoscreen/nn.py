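"""Small CPU neural-network library: layers, backprop, Adam.

Implements exactly what the fusion classifier needs — 1-D convolution,
max/average pooling, LSTM, dense layers, ReLU, dropout, softmax
cross-entropy and the Adam optimizer — in plain numpy with hand-written
gradients.  Everything is deterministic given a seeded
``numpy.random.Generator``; there is no hidden global state, so a full
train/predict cycle is reproducible bit-for-bit on CPU.

Array convention: batched time series are ``(batch, channels, length)``;
flat inputs are ``(batch, dim)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "Conv1D",
    "ReLU",
    "Dropout",
    "MaxPool1D",
    "AvgPool1D",
    "GlobalAvgPool1D",
    "Flatten",
    "LSTM",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(out_channels, in_channels, kernel)))
        self.b = Param(np.zeros(out_channels))
        self.kernel = kernel

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, L) -> (B, F, L - k + 1)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self._cols = cols  # (B, C, L', k)
        y = np.einsum("bclk,fck->bfl", cols, self.w.value, optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("bfl,bclk->fck", gy, self._cols, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        b, c, l_out, k = self._cols.shape
        gx = np.zeros((b, c, l_out + k - 1))
        for j in range(k):
            gx[:, :, j:j + l_out] += np.einsum(
                "bfl,fc->bcl", gy, self.w.value[:, :, j], optimize=True
            )
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout fraction must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        l_trim = (l // self.pool) * self.pool
        self._in_len = l
        xr = x[:, :, :l_trim].reshape(b, c, l_trim // self.pool, self.pool)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, l_out = gy.shape
        gx = np.zeros((b, c, l_out, self.pool))
        np.put_along_axis(gx, self._argmax[..., None], gy[..., None], axis=3)
        gx = gx.reshape(b, c, l_out * self.pool)
        if gx.shape[2] < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, self._in_len - gx.shape[2])))
        return gx


class AvgPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        l_trim = (l // self.pool) * self.pool
        self._in_len = l
        return x[:, :, :l_trim].reshape(b, c, -1, self.pool).mean(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.repeat(gy, self.pool, axis=2) / self.pool
        if gx.shape[2] < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, self._in_len - gx.shape[2])))
        return gx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, :, None], self._len, axis=2) / self._len


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single-layer LSTM over (batch, channels, time); returns last hidden.

    Gate order i, f, g, o; forget-gate bias initialized to 1 so memory is
    open at the start of training.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        if hidden < 1:
            raise ValueError("lstm hidden size must be >= 1")
        scale = 1.0 / np.sqrt(n_in + hidden)
        self.wx = Param(rng.normal(0.0, scale, size=(n_in, 4 * hidden)))
        self.wh = Param(rng.normal(0.0, scale, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Param(b)
        self.hidden = hidden

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, t_len = x.shape
        h_dim = self.hidden
        h = np.zeros((b, h_dim))
        cell = np.zeros((b, h_dim))
        self._cache = []
        self._x_shape = x.shape
        for t in range(t_len):
            xt = x[:, :, t]
            z = xt @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim:2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim:])
            c_prev = cell
            cell = f * c_prev + i * g
            h_prev = h
            h = o * np.tanh(cell)
            self._cache.append((xt, h_prev, c_prev, i, f, g, o, cell))
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t_len = self._x_shape
        h_dim = self.hidden
        gx = np.zeros(self._x_shape)
        dh = gy
        dc = np.zeros((b, h_dim))
        for t in range(t_len - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, cell = self._cache[t]
            tc = np.tanh(cell)
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += xt.T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            gx[:, :, t] = dz @ self.wx.value.T
            dh = dz @ self.wh.value.T
        return gx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-300).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad * p.grad
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
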