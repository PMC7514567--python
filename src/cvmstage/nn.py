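"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly what the compact staging CNN needs: 3x3 same-padding
convolution (im2col + GEMM), batch normalization, 2x2 max pooling, inverted
dropout, dense layers, ReLU, and the fused softmax + cross-entropy gradient,
plus SGD-with-momentum and Adam parameter updates. Layout is NHWC and all
parameters/activations are float32 so the heavy lifting happens inside BLAS
sgemm calls.

Not a general framework: layers cache what their backward pass needs and a
model is just an ordered list of layers.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base layer; subclasses fill ``params``/``grads`` dicts as needed."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        """Copy of learnable parameters plus any running buffers."""
        return {"params": copy.deepcopy(self.params)}

    def load_state(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k][...] = v

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patch matrix, zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * x.shape[3])


class Conv2D(Layer):
    """3x3 (or kxk, odd k) same-padding convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel side must be odd")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        #: set False on the input layer: no layer below needs its gradient
        self.compute_input_grad = True
        fan_in = k * k * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.params = {"W": w.astype(F32), "b": np.zeros(c_out, dtype=F32)}
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, training, rng):
        n, h, w, _ = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.params["W"] + self.params["b"]
        self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, _ = self._shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        self._cols = None
        if not self.compute_input_grad:
            return None
        # dX = full correlation of dout with the spatially flipped kernel
        k = self.k
        w4 = self.params["W"].reshape(k, k, self.c_in, self.c_out)
        w_rot = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(k * k * self.c_out,
                                                          self.c_in)
        cols_d = _im2col(dout, k)
        return (cols_d @ w_rot).reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over all but the channel (last) axis."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels, dtype=F32),
                       "beta": np.zeros(channels, dtype=F32)}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache: tuple | None = None

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            # single-pass variance; activations are O(1) so this is safe
            var = np.maximum((x * x).mean(axis=axes) - mean * mean, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat.astype(F32), inv_std.astype(F32), axes)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(F32)

    def backward(self, dout):
        xhat, inv_std, axes = self._cache
        self._cache = None
        m = float(np.prod([dout.shape[a] for a in axes]))
        dbeta = dout.sum(axis=axes)
        dgamma = (dout * xhat).sum(axis=axes)
        self.grads["gamma"], self.grads["beta"] = dgamma, dbeta
        dx = (self.params["gamma"] * inv_std / m) * (
            m * dout - dbeta - xhat * dgamma)
        return dx.astype(F32)

    def state(self):
        return {"params": copy.deepcopy(self.params),
                "running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_state(self, state):
        super().load_state(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class MaxPool2D(Layer):
    """Non-overlapping side x side max pooling (side 1 = identity)."""

    def __init__(self, side: int = 2) -> None:
        super().__init__()
        self.side = side
        self._mask: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, training, rng):
        s = self.side
        if s == 1:
            return x
        n, h, w, c = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool {s}")
        xr = x.reshape(n, h // s, s, w // s, s, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // s, w // s, s * s, c)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._mask = (idx[:, :, :, None, :]
                          == np.arange(s * s)[None, None, None, :, None])
            self._shape = x.shape
        return out

    def backward(self, dout):
        s = self.side
        if s == 1:
            return dout
        n, h, w, c = self._shape
        dxr = self._mask * dout[:, :, :, None, :]
        self._mask = None
        dxr = dxr.reshape(n, h // s, w // s, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dxr).reshape(n, h, w, c).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode and at rate 0."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(F32), "b": np.zeros(n_out, dtype=F32)}
        self._x: np.ndarray | None = None

    def forward(self, x, training, rng):
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x, training, rng):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray,
                          eps: float = 1e-12) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, its gradient w.r.t. logits, and the probs."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, eps, 1.0))).sum() / n)
    dlogits = ((probs - onehot) / n).astype(F32)
    return loss, dlogits, probs


class Optimizer:
    def __init__(self, layers: list[Layer], learning_rate: float) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = learning_rate

    def step(self) -> None:
        raise NotImplementedError

    def state(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


class SGD(Optimizer):
    """SGD with classical momentum: v <- mu v - lr g; p <- p + v."""

    def __init__(self, layers, learning_rate, momentum: float = 0.9) -> None:
        super().__init__(layers, learning_rate)
        self.momentum = momentum
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()}
                  for l in self.layers]

    def step(self):
        for l, vel in zip(self.layers, self.v):
            for k, p in l.params.items():
                vel[k] = (self.momentum * vel[k]
                          - self.lr * l.grads[k]).astype(F32)
                p += vel[k]

    def state(self):
        return {"v": copy.deepcopy(self.v)}

    def load_state(self, state):
        self.v = copy.deepcopy(state["v"])


class Adam(Optimizer):
    def __init__(self, layers, learning_rate, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__(layers, learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = (b1 * m[k] + (1 - b1) * g).astype(F32)
                v[k] = (b2 * v[k] + (1 - b2) * g * g).astype(F32)
                p -= (self.lr * (m[k] / bc1)
                      / (np.sqrt(v[k] / bc2) + self.eps)).astype(F32)

    def state(self):
        return {"t": self.t, "m": copy.deepcopy(self.m),
                "v": copy.deepcopy(self.v)}

    def load_state(self, state):
        self.t = state["t"]
        self.m = copy.deepcopy(state["m"])
        self.v = copy.deepcopy(state["v"])
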