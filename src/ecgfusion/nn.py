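"""A small, self-contained neural-network layer library on numpy.

Provides exactly what the feature-merging CNN needs: 2-D convolution (im2col),
ReLU, max pooling, batch normalization, residual blocks, global average
pooling, dense layers, sigmoid, and inverted dropout — each with forward and
backward passes — plus plain SGD.  Everything is seeded through
``numpy.random.Generator``; a fixed seed gives bit-identical training runs on
one device.

Tensor convention: images are ``(B, C, H, W)`` float64; dense activations are
``(B, D)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ReLU", "MaxPool2d", "BatchNorm2d", "GlobalAvgPool",
    "Dense", "Sigmoid", "Dropout", "Flatten", "Sequential", "ResidualBlock",
    "sgd_step", "bce_loss",
]


class Layer:
    """Base layer. Subclasses implement forward/backward and list params."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        """List of {"value": array, "grad": array} dicts, updated in place."""
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (b, c, ho, wo, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return cols, ho, wo, x.shape


def _col2im(cols: np.ndarray, x_padded_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    b, c, hp, wp = x_padded_shape
    out = np.zeros((b, c, hp, wp))
    cols = cols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, :, :, i, j]
    return out[:, :, pad : hp - pad if pad else hp, pad : wp - pad if pad else wp]


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.w = rng.normal(0, scale, (cout, cin * k * k))
        self.b = np.zeros(cout) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x, train=False):
        cols, ho, wo, pshape = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (cols, ho, wo, pshape, x.shape[0])
        out = cols @ self.w.T
        if self.b is not None:
            out = out + self.b
        return out.reshape(x.shape[0], ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, ho, wo, pshape, b = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.gw[...] = g.T @ cols
        if self.b is not None:
            self.gb[...] = g.sum(axis=0)
        dcols = g @ self.w
        return _col2im(dcols, pshape, self.k, self.stride, self.pad, ho, wo)

    def params(self):
        p = [{"value": self.w, "grad": self.gw}]
        if self.b is not None:
            p.append({"value": self.b, "grad": self.gb})
        return p


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    def __init__(self, k: int = 2, stride: int | None = None, pad: int = 0):
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                       constant_values=-np.inf)
        ho = (x.shape[2] - self.k) // self.stride + 1
        wo = (x.shape[3] - self.k) // self.stride + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride][:, :, :ho, :wo]
        flat = win.reshape(b, c, ho, wo, -1)
        self._argmax = flat.argmax(axis=-1)
        self._xshape, self._pshape = (b, c, h, w), x.shape
        self._ho, self._wo = ho, wo
        return flat.max(axis=-1)

    def backward(self, grad):
        b, c, h, w = self._xshape
        out = np.zeros(self._pshape)
        ho, wo = self._ho, self._wo
        bi, ci, hi, wi = np.indices((b, c, ho, wo))
        di, dj = np.unravel_index(self._argmax, (self.k, self.k))
        out[bi, ci, hi * self.stride + di, wi * self.stride + dj] += grad
        if self.pad:
            out = out[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return out


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma, self.beta = np.ones(ch), np.zeros(ch)
        self.ggamma, self.gbeta = np.zeros(ch), np.zeros(ch)
        self.run_mean, self.run_var = np.zeros(ch), np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        m, v = mean[None, :, None, None], var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._std = np.sqrt(v + self.eps)
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.ggamma[...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = grad * g
        return (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)) / self._std

    def params(self):
        return [{"value": self.gamma, "grad": self.ggamma},
                {"value": self.beta, "grad": self.gbeta}]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(2.0 / din), (din, dout))
        self.b = np.zeros(dout)
        self.gw, self.gb = np.zeros_like(self.w), np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [{"value": self.w, "grad": self.gw},
                {"value": self.b, "grad": self.gb}]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class ResidualBlock(Layer):
    """y = ReLU(main(x) + shortcut(x)); shortcut defaults to identity."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main, self.shortcut = main, shortcut
        self.relu = ReLU()

    def forward(self, x, train=False):
        y = self.main.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut else x
        return self.relu.forward(y + s, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        gmain = self.main.backward(grad)
        gshort = self.shortcut.backward(grad) if self.shortcut else grad
        return gmain + gshort

    def params(self):
        p = self.main.params()
        if self.shortcut:
            p += self.shortcut.params()
        return p


def bce_loss(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy and its gradient w.r.t. the sigmoid output."""
    p = np.clip(p, 1e-7, 1 - 1e-7)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = (p - y) / (p * (1 - p)) / len(p)
    return loss, grad


def sgd_step(params: list[dict], lr: float, clip_norm: float | None = 5.0) -> None:
    """One SGD update; gradients are globally norm-clipped for stability."""
    if clip_norm is not None:
        total = np.sqrt(sum(float(np.sum(p["grad"] ** 2)) for p in params))
        if total > clip_norm:
            scale = clip_norm / total
            for p in params:
                p["grad"] *= scale
    for p in params:
        p["value"] -= lr * p["grad"]
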