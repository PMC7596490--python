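"""Minimal numpy neural-network engine for the window classifier.

Implements exactly the layers the VT network needs — valid 1D convolution,
ReLU, non-overlapping 1D max pooling, a single-layer LSTM read out at its
final hidden state, and dense layers — with hand-written backward passes
and an RMSprop optimizer.  Layers follow the dtype of their inputs and
parameters (float32 for training throughput, float64 when checking
gradients against central finite differences); everything is deterministic.

Array convention: sequence tensors are ``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "MaxPool1D", "LSTM", "Dense", "RMSprop",
           "sigmoid", "bce_loss"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross entropy."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: parameters live in ``params`` with matching ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Conv1D(Layer):
    """Valid 1D correlation computed as k shifted matmuls.

    The shift-and-sum form (one ``(B*Lo, Cin) @ (Cin, Cout)`` product per
    kernel tap) avoids materializing im2col columns, which dominates memory
    traffic for long input sequences.  ``compute_dx=False`` skips the input
    gradient; use it for the layer that touches the raw signal.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, compute_dx: bool = True):
        super().__init__()
        self.k = kernel_size
        self.cin = in_channels
        self.cout = out_channels
        self.compute_dx = compute_dx
        fan_in = kernel_size * in_channels
        self.params["W"] = _glorot(rng, (kernel_size, in_channels, out_channels),
                                   fan_in, out_channels)
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, L, _ = x.shape
        Lo = L - self.k + 1
        W = self.params["W"]
        y = np.zeros((B, Lo, self.cout), dtype=x.dtype)
        for t in range(self.k):
            y += x[:, t: t + Lo, :] @ W[t]
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, Lo, cout = dy.shape
        W = self.params["W"]
        dW = np.empty_like(W)
        flat_dy = dy.reshape(B * Lo, cout)
        for t in range(self.k):
            xt = x[:, t: t + Lo, :].reshape(B * Lo, self.cin)
            dW[t] = xt.T @ flat_dy
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        if not self.compute_dx:
            return None
        dx = np.zeros_like(x)
        for t in range(self.k):
            dx[:, t: t + Lo, :] += dy @ W[t].T
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis.

    A trailing remainder shorter than the pool width is dropped, mirroring
    the window-tiling convention used throughout the pipeline.
    """

    def __init__(self, pool: int):
        super().__init__()
        self.p = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.p
        if Lo < 1:
            raise ValueError("pooling would reduce the sequence below 1 step")
        self._in_len = L
        xr = x[:, : Lo * self.p].reshape(B, Lo, self.p, C)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Lo, C = dy.shape
        dxr = np.zeros((B, Lo, self.p, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dx[:, : Lo * self.p] = dxr.reshape(B, Lo * self.p, C)
        return dx


class LSTM(Layer):
    """Single-layer LSTM; only the final hidden state is emitted.

    Gate order in the packed weight matrices is (input, forget, cell,
    output); the forget gate carries a +1 bias at initialization.
    """

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.u = units
        self.params["Wx"] = _glorot(rng, (in_features, 4 * units),
                                    in_features, units)
        self.params["Wh"] = _glorot(rng, (units, 4 * units), units, units)
        b = np.zeros(4 * units)
        b[units: 2 * units] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        u = self.u
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        self._x = x
        self._steps = []
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u: 2 * u])
            g = np.tanh(z[:, 2 * u: 3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._steps.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        self._hT = h
        return h

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        u = self.u
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dh_out.copy()
        dc = np.zeros((B, u), dtype=dh.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, (in_features, out_features),
                                   in_features, out_features)
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class RMSprop:
    """RMSprop: w -= lr * g / (sqrt(rho*v + (1-rho)*g^2) + eps).

    ``weight_decay`` applies decoupled L2 shrinkage (w *= 1 - lr*decay)
    to weight matrices (not biases) after each step.
    """

    def __init__(self, layers: list[Layer], learning_rate: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = layers
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self.cache = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]

    def step(self) -> None:
        shrink = 1.0 - self.lr * self.weight_decay
        for layer, cache in zip(self.layers, self.cache):
            for k, g in layer.grads.items():
                cache[k] = self.rho * cache[k] + (1.0 - self.rho) * g ** 2
                layer.params[k] -= self.lr * g / (np.sqrt(cache[k]) + self.eps)
                if self.weight_decay and not k.startswith("b"):
                    layer.params[k] *= shrink
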