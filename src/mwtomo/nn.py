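"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for a small image-to-image U-Net: stride-1
convolutions (im2col with arbitrary padding), batch normalization,
ReLU, 2x2 max pooling, nearest-neighbour upsampling, and an Adam
optimizer.  All arrays are float64 NCHW; layers cache what their
backward pass needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "UpsampleNN2",
    "Sequential",
    "Adam",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list:
        return []

    def gradients(self) -> list:
        return []


class Conv2d(Layer):
    """Stride-1 2D convolution (cross-correlation) with explicit padding.

    ``pad`` is ((top, bottom), (left, right)).  A 3x3 kernel with pad 1
    preserves the spatial size; a 2x2 kernel with pad ((0,1),(0,1)) does
    too (the convention used after upsampling).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, pad, rng: np.random.Generator):
        if isinstance(pad, int):
            pad = ((pad, pad), (pad, pad))
        self.pad = pad
        self.k = k
        # He initialisation for ReLU networks
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.w = rng.standard_normal((out_ch, in_ch, k, k)) * std
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._win = None

    def forward(self, x, train):
        (pt, pb), (pl, pr) = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        if train:
            self._win = win
        return (
            np.einsum("bchwij,ocij->bohw", win, self.w, optimize=True)
            + self.b[None, :, None, None]
        )

    def backward(self, grad):
        self.gw[...] = np.einsum(
            "bchwij,bohw->ocij", self._win, grad, optimize=True
        )
        self.gb[...] = grad.sum(axis=(0, 2, 3))
        # input gradient: full correlation of grad with the flipped kernel
        (pt, pb), (pl, pr) = self.pad
        k = self.k
        gp = np.pad(grad, ((0, 0), (0, 0), (k - 1 - pt, k - 1 - pb),
                           (k - 1 - pl, k - 1 - pr)))
        gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
        wflip = self.w[:, :, ::-1, ::-1]
        gx = np.einsum("bohwij,ocij->bchw", gwin, wflip, optimize=True)
        self._win = None
        return gx

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.ggamma = np.zeros(ch)
        self.gbeta = np.zeros(ch)
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        self._cache = None
        m = shape[0] * shape[2] * shape[3]
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma[None, :, None, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return gx

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.ggamma, self.gbeta]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input sizes must be even."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x, train):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax = idx
            self._shape = x.shape
        return out

    def backward(self, grad):
        b, c, h, w = self._shape
        flat = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        gx = (
            flat.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        self._argmax = None
        return gx


class UpsampleNN2(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        b, c, h, w = grad.shape
        return grad.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [g for l in self.layers for g in l.gradients()]


class Adam:
    """Adaptive-moment optimizer updating parameter arrays in place."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
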