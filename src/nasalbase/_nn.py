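"""Minimal seeded neural-network layers for desk-scale CPU training.

Deliberately small: 2-D convolution (im2col), LeakyReLU, dense layers,
Adam, MAE loss, and the named learning-rate schedule families.  Arrays
are float32 NCHW; everything is deterministic given the initialization
seed, so training twice with the same seed reproduces losses exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "Dense", "LeakyReLU", "Flatten", "Sequential",
    "Adam", "sigmoid", "mae_loss", "lr_schedule",
]


class Layer:
    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution with 'same' zero padding and stride."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0, scale, (cout, cin * k * k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.W, "grad": lambda: self.gW},
                {"value": self.b, "grad": lambda: self.gb}]

    def _im2col(self, xp: np.ndarray, hout: int, wout: int) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, hout, wout, k, k)
        return win.transpose(0, 1, 4, 5, 2, 3).reshape(
            xp.shape[0], self.cin * k * k, hout * wout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        n, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hout = (h + 2 * p - k) // s + 1
        wout = (w + 2 * p - k) // s + 1
        self._shape = (n, c, h, w, hout, wout)
        self._cols = self._im2col(xp, hout, wout)
        out = np.einsum("oc,ncl->nol", self.W, self._cols) + self.b[None, :, None]
        return out.reshape(n, self.cout, hout, wout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w, hout, wout = self._shape
        k, s = self.k, self.stride
        p = k // 2
        g = grad.reshape(n, self.cout, hout * wout)
        self.gW = np.einsum("nol,ncl->oc", g, self._cols)
        self.gb = g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", self.W, g)
        dcols = dcols.reshape(n, c, k, k, hout, wout)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + hout * s:s, j:j + wout * s:s] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / nin), (nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.W, "grad": lambda: self.gW},
                {"value": self.b, "grad": lambda: self.gb}]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[dict], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]()
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=x.dtype if np.issubdtype(np.asarray(x).dtype, np.floating) else float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


def lr_schedule(name: str, base_lr: float, epochs: int,
                step_every: int = 10, step_factor: float = 0.5,
                poly_power: float = 2.0, exp_gamma: float = 0.95):
    """Named learning-rate schedule families.

    ``standard`` is constant; ``linear`` and ``polynomial`` decay to 0
    over the run; ``step`` halves every ``step_every`` epochs;
    ``exponential`` multiplies by ``exp_gamma`` each epoch.
    """
    def f(epoch: int) -> float:
        if name == "standard":
            return base_lr
        if name == "linear":
            return base_lr * max(0.0, 1.0 - epoch / max(1, epochs))
        if name == "step":
            return base_lr * step_factor ** (epoch // step_every)
        if name == "polynomial":
            return base_lr * max(0.0, 1.0 - epoch / max(1, epochs)) ** poly_power
        if name == "exponential":
            return base_lr * exp_gamma ** epoch
        raise ValueError(f"unknown schedule {name!r}")
    return f
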