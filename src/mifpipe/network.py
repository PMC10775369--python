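"""Three-head encoder-decoder network for cell segmentation.

A U-Net-style shared encoder feeds three heads:

* a segmentation decoder with skip connections producing per-pixel logits
  for {background, cell interior, cell boundary};
* a cell-count regressor (global average pool of the bottleneck, dense
  layer, softplus so the count is non-negative);
* an auto-encoding decoder (no skips — it must reconstruct the input from
  the bottleneck alone, regularizing the shared features).

The network takes two input channels — the pan-leukocyte membrane stain
(CD45) and the nuclear stain (DAPI) — as normalized [0, 1] images.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .nn import (Adam, Concat, Conv2D, GlobalAvgPool, Linear, MaxPool2,
                 Param, ReLU, Upsample2, softmax_channels, softplus,
                 softplus_grad)


@dataclass
class ArchConfig:
    in_channels: int = 2
    base_filters: int = 32
    depth: int = 4          # number of 2x poolings
    tile_size: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.tile_size < 2 ** self.depth:
            raise ValueError(
                f"tile size {self.tile_size} incompatible with pooling "
                f"depth {self.depth} (must be at least {2 ** self.depth})")


class MultiTaskUNet:
    """Shared encoder, segmentation decoder with skips, count and
    auto-encoding heads from the bottleneck."""

    def __init__(self, config: ArchConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base, cin = config.depth, config.base_filters, config.in_channels
        ch = [base * 2 ** l for l in range(d)]
        cb = base * 2 ** d

        def conv(ci, co, k=3):
            return Conv2D(ci, co, k, rng)

        self.enc = []
        prev = cin
        for l in range(d):
            self.enc.append((conv(prev, ch[l]), ReLU(),
                             conv(ch[l], ch[l]), ReLU()))
            prev = ch[l]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bott = (conv(prev, cb), ReLU(), conv(cb, cb), ReLU())

        self.dec = []
        prev = cb
        for l in reversed(range(d)):
            self.dec.append((Upsample2(), Concat(),
                             conv(prev + ch[l], ch[l]), ReLU(),
                             conv(ch[l], ch[l]), ReLU()))
            prev = ch[l]
        self.seg_head = Conv2D(prev, 3, 1, rng)

        self.gap = GlobalAvgPool()
        self.count_fc = Linear(cb, 1, rng)

        self.rec = []
        prev = cb
        for l in reversed(range(d)):
            self.rec.append((Upsample2(), conv(prev, ch[l]), ReLU()))
            prev = ch[l]
        self.rec_head = Conv2D(prev, cin, 1, rng)

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> List[Param]:
        out = []
        for block in self.enc:
            for layer in block:
                out.extend(layer.params())
        for layer in self.bott:
            out.extend(layer.params())
        for block in self.dec:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.seg_head.params())
        out.extend(self.count_fc.params())
        for block in self.rec:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.rec_head.params())
        return out

    def l2_norm(self) -> float:
        """Sum of squared weights (the Lreg term)."""
        return float(sum((p.value.astype(np.float64) ** 2).sum()
                         for p in self.params() if p.decay))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> Dict[str, np.ndarray]:
        """x: (B, in_channels, H, W) float32.

        Inputs are reflect-padded internally to a multiple of 2^depth and
        the dense outputs cropped back. Returns seg_logits (B,3,H,W),
        count (B,1) and recon (B,cin,H,W).
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        m = 2 ** self.config.depth
        H, W = x.shape[2], x.shape[3]
        ph, pw = (-H) % m, (-W) % m
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       mode="reflect")
        a = x
        skips = []
        for block, pool in zip(self.enc, self.pools):
            c1, r1, c2, r2 = block
            a = r2.forward(c2.forward(r1.forward(c1.forward(a))))
            skips.append(a)
            a = pool.forward(a)
        c1, r1, c2, r2 = self.bott
        b = r2.forward(c2.forward(r1.forward(c1.forward(a))))

        pooled = self.gap.forward(b)
        self._count_z = self.count_fc.forward(pooled)
        count = softplus(self._count_z)

        dcur = b
        for block, skip in zip(self.dec, reversed(skips)):
            up, cat, c1, r1, c2, r2 = block
            dcur = cat.forward(up.forward(dcur), skip)
            dcur = r2.forward(c2.forward(r1.forward(c1.forward(dcur))))
        seg_logits = self.seg_head.forward(dcur)

        rcur = b
        for up, conv_, relu_ in self.rec:
            rcur = relu_.forward(conv_.forward(up.forward(rcur)))
        recon = self.rec_head.forward(rcur)

        if ph or pw:
            seg_logits = seg_logits[:, :, :H, :W]
            recon = recon[:, :, :H, :W]
        return {"seg_logits": seg_logits, "count": count, "recon": recon}

    def backward(self, d_seg: np.ndarray, d_count: np.ndarray,
                 d_recon: np.ndarray) -> None:
        """Accumulate parameter gradients given output gradients."""
        ph, pw = self._pad
        if ph or pw:
            # cropping's adjoint: zero-pad gradients back to padded size
            d_seg = np.pad(d_seg, ((0, 0), (0, 0), (0, ph), (0, pw)))
            d_recon = np.pad(d_recon, ((0, 0), (0, 0), (0, ph), (0, pw)))
        g = self.seg_head.backward(d_seg.astype(np.float32))
        skip_grads = []
        for block in reversed(self.dec):
            up, cat, c1, r1, c2, r2 = block
            g = c1.backward(r1.backward(c2.backward(r2.backward(g))))
            g, gs = cat.backward(g)
            g = up.backward(g)
            skip_grads.append(gs)
        gb = g  # gradient arriving at the bottleneck from the seg decoder

        dz = (d_count * softplus_grad(self._count_z)).astype(np.float32)
        gb = gb + self.gap.backward(self.count_fc.backward(dz))

        g = self.rec_head.backward(d_recon.astype(np.float32))
        for up, conv_, relu_ in reversed(self.rec):
            g = up.backward(conv_.backward(relu_.backward(g)))
        gb = gb + g

        c1, r1, c2, r2 = self.bott
        g = c1.backward(r1.backward(c2.backward(r2.backward(gb))))
        for block, pool, gs in zip(reversed(self.enc), reversed(self.pools),
                                   skip_grads[::-1]):
            c1, r1, c2, r2 = block
            g = pool.backward(g) + gs
            g = c1.backward(r1.backward(c2.backward(r2.backward(g))))

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (B, 3, H, W)."""
        return softmax_channels(self.forward(x)["seg_logits"])

    # -- checkpointing -----------------------------------------------------
    def get_weights(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config,
                         "weights": self.get_weights()}, fh)

    @classmethod
    def load(cls, path) -> "MultiTaskUNet":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"])
        model.set_weights(blob["weights"])
        return model


def build_network(config: ArchConfig) -> MultiTaskUNet:
    """Construct the three-head network; raises if the configured tile size
    is incompatible with the pooling depth."""
    return MultiTaskUNet(config)
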