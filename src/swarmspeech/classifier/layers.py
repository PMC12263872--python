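"""Minimal NumPy layer library for the 1D CNN + LSTM classifier.

Tensors are channels-last: (batch, time, channels).  Every layer exposes
``forward(x, training)`` and ``backward(grad)`` plus aligned ``params`` /
``grads`` lists for the optimizer.  Shapes are fixed after the first
forward pass; there is no autograd, each backward is written out.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "BatchNorm1D",
    "TemporalAvgPool",
    "GlobalAvgPool",
    "LSTM",
    "Dense",
    "Adam",
    "sigmoid",
]


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded stride-1 1D convolution (cross-correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng):
        super().__init__()
        self.kernel_size = kernel_size
        limit = np.sqrt(6.0 / (kernel_size * in_channels + out_channels))
        self.w = rng.uniform(-limit, limit, size=(kernel_size, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size - 1 - self.pad_left

    def forward(self, x, training: bool):
        self._xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        t = x.shape[1]
        out = np.tensordot(self._xp[:, 0:t, :], self.w[0], axes=([2], [0]))
        for k in range(1, self.kernel_size):
            out += np.tensordot(self._xp[:, k : k + t, :], self.w[k], axes=([2], [0]))
        return out + self.b

    def backward(self, grad):
        t = grad.shape[1]
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel_size):
            self.grads[0][k] = np.einsum("bti,bto->io", self._xp[:, k : k + t, :], grad)
            dxp[:, k : k + t, :] += grad @ self.w[k].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        if self.pad_right:
            return dxp[:, self.pad_left : -self.pad_right, :]
        return dxp[:, self.pad_left :, :]


class ReLU(Layer):
    def forward(self, x, training: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder frames dropped."""

    def __init__(self, pool_size: int):
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x, training: bool):
        p = self.pool_size
        if p == 1:
            self._shape = x.shape
            self._argmax = None
            return x
        b, t, c = x.shape
        t_out = t // p
        self._shape = x.shape
        xr = x[:, : t_out * p, :].reshape(b, t_out, p, c)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        if self.pool_size == 1:
            return grad
        b, t, c = self._shape
        p = self.pool_size
        t_out = t // p
        dxr = np.zeros((b, t_out, p, c))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((b, t, c))
        dx[:, : t_out * p, :] = dxr.reshape(b, t_out * p, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; active only while training."""

    def __init__(self, rate: float, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training: bool):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm1D(Layer):
    """Per-channel normalization over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training: bool):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean) / self._std
            self._n = x.shape[0] * x.shape[1]
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        self.grads[0][...] = (grad * self._xhat).sum(axis=(0, 1))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        n = self._n
        dxhat = grad * self.gamma
        return (
            dxhat - dxhat.mean(axis=(0, 1)) - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1))
        ) / self._std


class TemporalAvgPool(Layer):
    """Sequence-preserving average pooling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x, training: bool):
        f = self.factor
        if f == 1:
            self._shape = x.shape
            return x
        b, t, c = x.shape
        self._shape = x.shape
        t_out = t // f
        return x[:, : t_out * f, :].reshape(b, t_out, f, c).mean(axis=2)

    def backward(self, grad):
        if self.factor == 1:
            return grad
        b, t, c = self._shape
        f = self.factor
        t_out = t // f
        dx = np.zeros((b, t, c))
        dx[:, : t_out * f, :] = np.repeat(grad / f, f, axis=1)
        return dx


class GlobalAvgPool(Layer):
    """Collapse the whole time axis to one step (the literal reading)."""

    def forward(self, x, training: bool):
        self._t = x.shape[1]
        return x.mean(axis=1, keepdims=True)

    def backward(self, grad):
        return np.repeat(grad / self._t, self._t, axis=1)


class LSTM(Layer):
    """Single-layer LSTM; gate order (input, forget, cell, output)."""

    def __init__(self, in_dim: int, hidden: int, rng, return_sequences: bool):
        super().__init__()
        self.hidden = hidden
        self.return_sequences = return_sequences
        limit = np.sqrt(6.0 / (in_dim + hidden))
        self.wx = rng.uniform(-limit, limit, size=(in_dim, 4 * hidden))
        self.wh = rng.uniform(-limit, limit, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training: bool):
        b, t, _ = x.shape
        h = self.hidden
        self._x = x
        self._cache = []
        h_t = np.zeros((b, h))
        c_t = np.zeros((b, h))
        out = np.empty((b, t, h))
        for step in range(t):
            a = x[:, step, :] @ self.wx + h_t @ self.wh + self.b
            i = sigmoid(a[:, :h])
            f = sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = sigmoid(a[:, 3 * h :])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h_t, c_t, i, f, g, o, tanh_c))
            c_t = c_new
            h_t = o * tanh_c
            out[:, step, :] = h_t
        if self.return_sequences:
            return out
        return out[:, -1, :]

    def backward(self, grad):
        x = self._x
        b, t, in_dim = x.shape
        h = self.hidden
        for g_arr in self.grads:
            g_arr[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[step]
            if self.return_sequences:
                dh = grad[:, step, :] + dh_next
            else:
                dh = (grad if step == t - 1 else 0.0) + dh_next
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            da = np.empty((b, 4 * h))
            da[:, :h] = dc * g * i * (1.0 - i)
            da[:, h : 2 * h] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * h : 3 * h] = dc * i * (1.0 - g**2)
            da[:, 3 * h :] = dh * tanh_c * o * (1.0 - o)
            self.grads[0] += x[:, step, :].T @ da
            self.grads[1] += h_prev.T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, step, :] = da @ self.wx.T
            dh_next = da @ self.wh.T
            dc_next = dc * f
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng, activation: str | None = None):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.w = rng.uniform(-limit, limit, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.activation = activation

    def forward(self, x, training: bool):
        self._x = x
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Adam:
    """Adaptive-moment gradient descent over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
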