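"""Minimal CPU autodiff engine for the convolutional denoisers.

Implements exactly the layers the denoisers need — 2-D convolution (via
im2col), ReLU, 2x2 max-pooling, nearest-neighbour upsampling and channel
concatenation — each with an explicit forward returning a cache and a
backward accumulating parameter gradients, plus an Adam optimizer.
Activations and weights are float32; gradient correctness is verified
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "relu_forward", "relu_backward", "MaxPool2d",
           "upsample2_forward", "upsample2_backward", "DoubleConv", "Adam"]


class Conv2d:
    """3x3 (or kxk) convolution, stride 1, zero padding k//2 (shape-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, ksize: int = 3,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = ksize
        fan_in = in_channels * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, scale, (out_channels, fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW.fill(0.0)
        self.gb.fill(0.0)

    def forward(self, x: np.ndarray):
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        if p > 0:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 3, 1, 4, 5)
        ).reshape(B, H * W, C * k * k)
        out = cols @ self.W.T + self.b                      # (B,HW,F)
        out = out.transpose(0, 2, 1).reshape(B, self.out_channels, H, W)
        return out, (cols, (B, C, H, W))

    def backward(self, gout: np.ndarray, cache, need_gx: bool = True):
        cols, (B, C, H, W) = cache
        k, p = self.k, self.k // 2
        g = gout.reshape(B, self.out_channels, H * W).transpose(0, 2, 1)  # (B,HW,F)
        self.gW += np.tensordot(g, cols, axes=([0, 1], [0, 1]))
        self.gb += g.sum(axis=(0, 1))
        if not need_gx:
            return None
        gcols = (g @ self.W).reshape(B, H, W, C, k, k)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=gout.dtype)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di:di + H, dj:dj + W] += \
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + H, p:p + W] if p > 0 else gxp


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(gout: np.ndarray, mask: np.ndarray):
    return gout * mask


class MaxPool2d:
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling: {H}x{W}")
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        return out, (idx, (B, C, H, W))

    def backward(self, gout: np.ndarray, cache):
        idx, (B, C, H, W) = cache
        g = np.zeros((B, C, H // 2, W // 2, 4), dtype=gout.dtype)
        np.put_along_axis(g, idx[..., None], gout[..., None], axis=-1)
        g = g.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g).reshape(B, C, H, W)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(gout: np.ndarray) -> np.ndarray:
    B, C, H, W = gout.shape
    return gout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class DoubleConv:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU, the standard U-Net block."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.c1 = Conv2d(in_channels, out_channels, 3, rng)
        self.c2 = Conv2d(out_channels, out_channels, 3, rng)

    def layers(self):
        return [self.c1, self.c2]

    def forward(self, x):
        h1, cc1 = self.c1.forward(x)
        a1, m1 = relu_forward(h1)
        h2, cc2 = self.c2.forward(a1)
        a2, m2 = relu_forward(h2)
        return a2, (cc1, m1, cc2, m2)

    def backward(self, gout, cache, need_gx=True):
        cc1, m1, cc2, m2 = cache
        g = relu_backward(gout, m2)
        g = self.c2.backward(g, cc2)
        g = relu_backward(g, m1)
        return self.c1.backward(g, cc1, need_gx=need_gx)


class Adam:
    """Adam with the usual defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, layers, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for lay in self.layers for p, _ in lay.params()]
        self.v = [np.zeros_like(p) for lay in self.layers for p, _ in lay.params()]

    def zero_grad(self):
        for lay in self.layers:
            lay.zero_grad()

    def step(self):
        self.t += 1
        i = 0
        for lay in self.layers:
            for p, g in lay.params():
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1 ** self.t)
                vhat = self.v[i] / (1 - self.b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1
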