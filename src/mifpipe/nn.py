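"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for the three-head segmentation network: 2-D
convolution (im2col + BLAS), ReLU, 2x2 max pooling, nearest-neighbour
2x upsampling, channel concatenation, global average pooling, a dense
layer, and an Adam optimizer with optional L2 weight decay. Arrays are
float32, layout (batch, channels, height, width). Every layer caches what
its backward pass needs on forward, so a layer instance is used exactly
once per forward pass.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A tensor parameter with an accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in the L2 regularization term

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Param]:
        return []


class Conv2D(Layer):
    """Same-padding stride-1 convolution, kernel k x k (k odd)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 weight_scale: Optional[float] = None):
        scale = weight_scale if weight_scale is not None \
            else np.sqrt(2.0 / (cin * k * k))
        self.k, self.cin, self.cout = k, cin, cout
        self.W = Param(rng.normal(0, scale, (cout, cin * k * k)), decay=True)
        self.b = Param(np.zeros(cout))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(B * H * W, C * k * k)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape)
        return out.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)
                                 ).reshape(B * H * W, self.cout)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + H, kj:kj + W] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W] if p else dxp

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; input spatial dims must be even."""

    def forward(self, x):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2) \
              .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (B, C, H, W)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        B, C, H, W = self._shape
        gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        return gr.reshape(B, C, H // 2, W // 2, 2, 2) \
                 .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        B, C, H, W = g.shape
        return g.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Concat(Layer):
    """Concatenate two tensors along the channel axis."""

    def forward(self, a, b):
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, g):
        return g[:, :self._split], g[:, self._split:]


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        B, C, H, W = self._shape
        return np.broadcast_to(g[:, :, None, None] / (H * W),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin, cout, rng, weight_scale=0.01):
        self.W = Param(rng.normal(0, weight_scale, (cout, cin)), decay=True)
        self.b = Param(np.zeros(cout))

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value

    def params(self):
        return [self.W, self.b]


def softplus(z):
    return np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)


def softplus_grad(z):
    return 1.0 / (1.0 + np.exp(-z))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of (B, K, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with decoupled gradient accumulation; ``l2`` adds 2*l2*w to the
    gradient of every decaying parameter (the derivative of l2 * sum w^2)."""

    def __init__(self, params: Sequence[Param], lr=1e-3, beta1=0.9,
                 beta2=0.999, eps=1e-8, l2=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + 2.0 * self.l2 * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
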