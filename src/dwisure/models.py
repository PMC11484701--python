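"""Denoiser architectures: a DnCNN-style residual CNN and a U-Net.

Both are fully convolutional, use no normalization layers (plain conv +
ReLU), and map an ``in_channels x H x W`` input — the noisy target image
optionally concatenated with lower-b-value guidance channels — to a
single denoised target channel. With ``residual=True`` (the DnCNN
convention) the network predicts the noise, which is subtracted from the
target channel, so a zero-weight network is the identity denoiser.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from ._net import (Adam, Conv2d, DoubleConv, MaxPool2d, relu_backward,
                   relu_forward, upsample2_backward, upsample2_forward)

__all__ = ["DenoiserConfig", "build_denoiser", "count_parameters",
           "DnCNN", "UNet", "save_checkpoint", "load_checkpoint"]


@dataclass
class DenoiserConfig:
    family: str = "dncnn"       # "dncnn" | "unet"
    depth: int = 17             # conv layers (dncnn)
    width: int = 64             # feature channels (dncnn) / base width (unet)
    in_channels: int = 2        # target + guidance channel(s)
    out_channels: int = 1
    residual: bool = True       # predict noise, subtract from target channel
    levels: int = 4             # resolution levels (unet)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("dncnn", "unet"):
            raise ValueError(f"unsupported denoiser family: {self.family!r}")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.out_channels != 1:
            raise ValueError("only a single output channel is supported")
        if self.family == "dncnn" and self.depth < 3:
            raise ValueError("dncnn depth must be >= 3")
        if self.family == "unet" and self.levels < 1:
            raise ValueError("unet needs >= 1 level")


class _NetworkBase:
    """Shared inference plumbing: float32 batching and the residual hook."""

    config: DenoiserConfig

    def layers(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def zero_grad(self) -> None:
        for lay in self.layers():
            lay.zero_grad()

    def __call__(self, y: np.ndarray) -> np.ndarray:
        """Denoise a single image: (H,W) or (C,H,W) -> (H,W)."""
        y = np.asarray(y, dtype=np.float32)
        squeeze_channel = y.ndim == 2
        if squeeze_channel:
            if self.config.in_channels != 1:
                raise ValueError(
                    f"network expects {self.config.in_channels} input channels; "
                    "pass a (C,H,W) array"
                )
            y = y[None]
        if y.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {y.shape[0]}"
            )
        out, _ = self.forward(y[None])
        return out[0, 0].astype(np.float64)


class DnCNN(_NetworkBase):
    """Plain conv/ReLU stack with a global residual connection.

    ``depth`` counts convolution layers: one input conv, ``depth - 2``
    hidden convs (all 3x3, ``width`` channels), and one output conv to a
    single channel. No pooling, so any H x W >= the receptive field works.
    """

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, c = config.width, config.in_channels
        self.convs = [Conv2d(c, w, 3, rng)]
        self.convs += [Conv2d(w, w, 3, rng) for _ in range(config.depth - 2)]
        self.convs.append(Conv2d(w, 1, 3, rng))
        if config.residual:
            # start near the identity denoiser (tiny noise prediction) so
            # early training is fidelity-stable, while keeping a nonzero
            # gradient path into the hidden layers
            self.convs[-1].W *= 0.01

    def layers(self):
        return self.convs

    def forward(self, x: np.ndarray):
        """x: (B, C, H, W) float32 -> (f, cache); f is (B, 1, H, W)."""
        caches = []
        h = x
        for conv in self.convs[:-1]:
            h, cc = conv.forward(h)
            h, mask = relu_forward(h)
            caches.append((cc, mask))
        out, cc_last = self.convs[-1].forward(h)
        caches.append(cc_last)
        if self.config.residual:
            f = x[:, :1] - out
        else:
            f = out
        return f, caches

    def backward(self, gf: np.ndarray, caches) -> None:
        """Accumulate parameter gradients of a scalar loss with gradient
        ``gf`` with respect to the network output ``f``."""
        g = -gf if self.config.residual else gf
        g = g.astype(np.float32)
        g = self.convs[-1].backward(g, caches[-1])
        for conv, (cc, mask) in zip(self.convs[-2::-1], caches[-2::-1]):
            g = relu_backward(g, mask)
            g = conv.backward(g, cc, need_gx=conv is not self.convs[0])


class UNet(_NetworkBase):
    """Encoder-decoder with skip connections and no normalization.

    ``levels`` encoder stages of width ``width * 2**i`` with 2x2
    max-pooling, a bottleneck of width ``width * 2**levels``, and a
    mirrored decoder using nearest-neighbour upsampling, a 3x3 channel-
    halving conv and skip concatenation. Input spatial dims must be
    divisible by ``2**levels``.
    """

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, L = config.width, config.levels
        widths = [w * 2 ** i for i in range(L)]
        self.enc = []
        c_in = config.in_channels
        for wi in widths:
            self.enc.append(DoubleConv(c_in, wi, rng))
            c_in = wi
        self.pool = MaxPool2d()
        self.bottleneck = DoubleConv(widths[-1], w * 2 ** L, rng)
        self.upconvs = []
        self.dec = []
        c_up = w * 2 ** L
        for wi in reversed(widths):
            self.upconvs.append(Conv2d(c_up, wi, 3, rng))
            self.dec.append(DoubleConv(2 * wi, wi, rng))
            c_up = wi
        self.final = Conv2d(widths[0], 1, 1, rng)
        if config.residual:
            # start near the identity denoiser (see DnCNN)
            self.final.W *= 0.01

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.layers())
        out.extend(self.bottleneck.layers())
        for up, blk in zip(self.upconvs, self.dec):
            out.append(up)
            out.extend(blk.layers())
        out.append(self.final)
        return out

    def forward(self, x: np.ndarray):
        L = self.config.levels
        if x.shape[2] % (2 ** L) or x.shape[3] % (2 ** L):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {2 ** L}"
            )
        skips, enc_caches, pool_caches = [], [], []
        h = x
        for blk in self.enc:
            h, cc = blk.forward(h)
            enc_caches.append(cc)
            skips.append(h)
            h, pc = self.pool.forward(h)
            pool_caches.append(pc)
        h, bott_cache = self.bottleneck.forward(h)
        up_caches, dec_caches = [], []
        for up, blk, skip in zip(self.upconvs, self.dec, reversed(skips)):
            h = upsample2_forward(h)
            h, uc = up.forward(h)
            h, um = relu_forward(h)
            up_caches.append((uc, um))
            h = np.concatenate([skip, h], axis=1)
            h, dc = blk.forward(h)
            dec_caches.append(dc)
        out, final_cache = self.final.forward(h)
        f = x[:, :1] - out if self.config.residual else out
        cache = (enc_caches, pool_caches, bott_cache, up_caches, dec_caches,
                 final_cache)
        return f, cache

    def backward(self, gf: np.ndarray, cache) -> None:
        (enc_caches, pool_caches, bott_cache, up_caches, dec_caches,
         final_cache) = cache
        g = (-gf if self.config.residual else gf).astype(np.float32)
        g = self.final.backward(g, final_cache)
        gskips = []
        for up, blk, (uc, um), dc in zip(self.upconvs[::-1], self.dec[::-1],
                                         up_caches[::-1], dec_caches[::-1]):
            g = blk.backward(g, dc)
            n_skip = g.shape[1] // 2
            gskips.append(g[:, :n_skip])
            g = relu_backward(g[:, n_skip:], um)
            g = up.backward(g, uc)
            g = upsample2_backward(g)
        g = self.bottleneck.backward(g, bott_cache)
        # the decoder was walked shallow-to-deep above, so gskips is already
        # ordered like self.enc
        for i in range(len(self.enc) - 1, -1, -1):
            g = self.pool.backward(g, pool_caches[i])
            g = g + gskips[i]
            g = self.enc[i].backward(g, enc_caches[i], need_gx=i > 0)


def build_denoiser(cfg: DenoiserConfig):
    """Instantiate a denoiser network from its configuration."""
    if cfg.family == "dncnn":
        return DnCNN(cfg)
    return UNet(cfg)


def count_parameters(net) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.size for lay in net.layers() for p, _ in lay.params()))


def make_optimizer(net, lr: float) -> Adam:
    return Adam(net.layers(), lr=lr)


def save_checkpoint(net, path: str, extra: dict | None = None) -> None:
    """Serialize weights (.npz) with a JSON sidecar of the configuration."""
    arrays = {}
    for i, lay in enumerate(net.layers()):
        for j, (p, _) in enumerate(lay.params()):
            arrays[f"p{i}_{j}"] = p
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    meta = {"config": asdict(net.config)}
    if extra:
        meta.update(extra)
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str):
    """Rebuild a denoiser from a checkpoint written by save_checkpoint."""
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg = DenoiserConfig(**meta["config"])
    net = build_denoiser(cfg)
    with np.load(base + ".npz") as data:
        for i, lay in enumerate(net.layers()):
            for j, (p, _) in enumerate(lay.params()):
                p[...] = data[f"p{i}_{j}"]
    return net, meta
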