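"""Composite segmentation loss.

The training objective combines five terms:

    L = Lce + alpha * Ljacc + lambda_c * Lcount + lambda_a * Lauto + beta * Lreg

* ``Lce`` — pixel-wise cross entropy over the three classes (background,
  cell interior, cell boundary). Interior and boundary pixels carry 3x
  weight against the dominant background class, and a boundary pixel
  currently predicted as interior carries a further 2x penalty (a constant
  per-pixel weight recomputed each forward pass, not differentiated
  through) so the network learns to keep touching cells separated.
* ``Ljacc`` — soft per-class Jaccard loss, 1 - |intersection|/|union| with
  probabilistic intersection/union and epsilon smoothing, averaged over
  the three classes.
* ``Lcount`` — squared error of the cell-count head against the number of
  instances in the tile.
* ``Lauto`` — mean squared reconstruction error of the auto-encoding head.
* ``Lreg`` — L2 norm of all network weights.

Default weights: alpha = 1e3, lambda_c = 1e3, lambda_a = 0.5, beta = 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

EPS = 1e-7


@dataclass
class LossWeights:
    alpha: float = 1e3          # Jaccard weight
    lambda_c: float = 1e3       # count weight
    lambda_a: float = 0.5       # autoencode weight
    beta: float = 1e-4          # L2 weight
    class_weights: Tuple[float, float, float] = (1.0, 3.0, 3.0)
    boundary_as_interior_multiplier: float = 2.0

    def __post_init__(self):
        vals = (self.alpha, self.lambda_c, self.lambda_a, self.beta,
                *self.class_weights, self.boundary_as_interior_multiplier)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")


def _canon(pred_probs: np.ndarray, target: np.ndarray):
    """Canonicalize to probs (B, 3, H, W) and target (B, H, W)."""
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(target)
    if p.ndim == 3:
        p = p[None]
    if y.ndim == 2:
        y = y[None]
    if p.shape[0] != y.shape[0] or p.shape[2:] != y.shape[1:]:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {y.shape}")
    return p, y


def _pixel_weights(p: np.ndarray, y: np.ndarray, w: LossWeights) -> np.ndarray:
    cw = np.asarray(w.class_weights, dtype=np.float64)
    weights = cw[y]
    pred = p.argmax(axis=1)
    weights = np.where((y == 2) & (pred == 1),
                       weights * w.boundary_as_interior_multiplier, weights)
    return weights


def weighted_cross_entropy(pred_probs: np.ndarray, target: np.ndarray,
                           weights: LossWeights) -> float:
    """Mean over pixels of w(px) * (-log p_true(px)).

    ``w`` is the true class's weight, doubled when a boundary pixel is
    currently argmax-predicted as interior.
    """
    p, y = _canon(pred_probs, target)
    w = _pixel_weights(p, y, weights)
    p_true = np.take_along_axis(p, y[:, None], axis=1)[:, 0]
    return float(np.mean(w * (-np.log(np.clip(p_true, EPS, None)))))


def jaccard_loss(pred_probs: np.ndarray, target: np.ndarray,
                 per_class: bool = False):
    """Soft per-class Jaccard loss, averaged over the three classes."""
    p, y = _canon(pred_probs, target)
    K = p.shape[1]
    out = np.empty(K)
    for k in range(K):
        yk = (y == k).astype(np.float64)
        pk = p[:, k]
        inter = float((pk * yk).sum())
        union = float(pk.sum() + yk.sum() - inter)
        out[k] = 1.0 - (inter + EPS) / (union + EPS)
    return out if per_class else float(out.mean())


def count_loss(predicted_count, n_instances) -> float:
    """Squared error of the count head against the tile's instance count."""
    c = np.asarray(predicted_count, dtype=np.float64).ravel()
    n = np.asarray(n_instances, dtype=np.float64).ravel()
    return float(np.mean((c - n) ** 2))


def autoencode_loss(reconstruction, original) -> float:
    """Mean squared reconstruction error."""
    r = np.asarray(reconstruction, dtype=np.float64)
    x = np.asarray(original, dtype=np.float64)
    if r.shape != x.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {x.shape}")
    return float(np.mean((r - x) ** 2))


def total_loss(lce: float, ljacc: float, lcount: float, lauto: float,
               lreg: float, w: LossWeights) -> float:
    return (lce + w.alpha * ljacc + w.lambda_c * lcount
            + w.lambda_a * lauto + w.beta * lreg)


# --- gradient versions used by the trainer -------------------------------

def seg_loss_grad(logits: np.ndarray, target: np.ndarray, w: LossWeights
                  ) -> Tuple[float, float, np.ndarray]:
    """(Lce, Ljacc, dL/dlogits) for the combined Lce + alpha*Ljacc term.

    ``logits`` is (B, 3, H, W); the gradient is averaged over the batch the
    same way the losses are.
    """
    from .nn import softmax_channels

    p = softmax_channels(logits.astype(np.float64))
    y = np.asarray(target)
    B, K, H, W = p.shape
    n_pix = B * H * W

    wpx = _pixel_weights(p, y, w)                     # (B, H, W)
    yh = np.zeros_like(p)
    np.put_along_axis(yh, y[:, None], 1.0, axis=1)
    p_true = np.take_along_axis(p, y[:, None], axis=1)[:, 0]
    lce = float(np.mean(wpx * (-np.log(np.clip(p_true, EPS, None)))))
    dlogits = wpx[:, None] * (p - yh) / n_pix          # CE grad wrt logits

    # soft Jaccard: grad wrt probs, then through the softmax Jacobian
    ljacc_terms = np.empty(K)
    gp = np.zeros_like(p)
    for k in range(K):
        yk = yh[:, k]
        pk = p[:, k]
        inter = (pk * yk).sum()
        union = pk.sum() + yk.sum() - inter
        ljacc_terms[k] = 1.0 - (inter + EPS) / (union + EPS)
        # d/dpk of -(I+eps)/(U+eps): dI=yk, dU=1-yk
        gp[:, k] = -(yk * (union + EPS) - (inter + EPS) * (1.0 - yk)) \
            / (union + EPS) ** 2
    gp /= K
    ljacc = float(ljacc_terms.mean())
    dlogits_j = p * (gp - (gp * p).sum(axis=1, keepdims=True))
    dlogits = dlogits + w.alpha * dlogits_j
    return lce, ljacc, dlogits.astype(np.float32)


def count_loss_grad(pred: np.ndarray, n: np.ndarray
                    ) -> Tuple[float, np.ndarray]:
    c = pred.astype(np.float64).ravel()
    n = np.asarray(n, dtype=np.float64).ravel()
    loss = float(np.mean((c - n) ** 2))
    grad = (2.0 * (c - n) / c.size).reshape(pred.shape)
    return loss, grad.astype(np.float32)


def autoencode_loss_grad(recon: np.ndarray, x: np.ndarray
                         ) -> Tuple[float, np.ndarray]:
    d = recon.astype(np.float64) - x.astype(np.float64)
    loss = float(np.mean(d ** 2))
    grad = (2.0 * d / d.size).astype(np.float32)
    return loss, grad
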