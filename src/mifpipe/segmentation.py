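"""Three-class cell segmentation: tiles, labels, training, instances.

Ground-truth class masks are derived from instance label maps: pixels
within ``boundary_width`` of an instance's outline become the boundary
class, the rest of the instance becomes interior, everything else is
background. The inverse conversion seeds connected interior components and
grows them through the boundary ring by watershed, so touching cells
separated only by a boundary ridge come back as distinct instances.

Fields of view are tiled into fixed-size windows with fractional overlap
both for training and for inference; at inference the per-tile softmax
probabilities are stitched back by averaging in overlap regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .losses import (LossWeights, autoencode_loss_grad, count_loss_grad,
                     seg_loss_grad, total_loss)
from .network import ArchConfig, MultiTaskUNet, build_network
from .nn import Adam, softmax_channels


@dataclass
class TrainConfig:
    tile_size: int = 300
    overlap_fraction: float = 0.2
    batch_size: int = 16
    epochs: int = 700
    learning_rate: float = 1e-5
    augment: bool = True
    noise_sd: float = 0.02        # augmentation: additive Gaussian noise
    mean_shift_sd: float = 0.05   # augmentation: global intensity offset
    val_fraction: float = 0.2
    restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")


@dataclass
class Tile:
    pixels: np.ndarray        # (C, tile, tile), zero-padded if needed
    row: int
    col: int
    valid: Tuple[int, int]    # unpadded extent (rows, cols)


def _offsets(dim: int, tile: int, stride: int) -> List[int]:
    if dim <= tile:
        return [0]
    offs = list(range(0, dim - tile, stride))
    last = dim - tile
    if not offs or offs[-1] != last:
        offs.append(last)
    return offs


def tile_image(img: np.ndarray, tile_size: int = 300,
               overlap: float = 0.2) -> List[Tile]:
    """Cover an image with overlapping tiles.

    stride = round(tile_size * (1 - overlap)); the last tile on each axis
    is anchored at max(0, dim - tile_size) so every pixel is covered.
    Images smaller than the tile are zero-padded; the valid extent is
    recorded on the tile.
    """
    img = np.asarray(img)
    single = img.ndim == 2
    if single:
        img = img[None]
    C, H, W = img.shape
    stride = max(1, int(round(tile_size * (1.0 - overlap))))
    tiles = []
    for r in _offsets(H, tile_size, stride):
        for c in _offsets(W, tile_size, stride):
            vh = min(tile_size, H - r)
            vw = min(tile_size, W - c)
            patch = np.zeros((C, tile_size, tile_size), dtype=img.dtype)
            patch[:, :vh, :vw] = img[:, r:r + vh, c:c + vw]
            tiles.append(Tile(patch[0] if single else patch, r, c, (vh, vw)))
    return tiles


def rasterize_labels(instances: np.ndarray, boundary_width: int = 2
                     ) -> np.ndarray:
    """Instance label map -> 3-class mask {0 bg, 1 interior, 2 boundary}.

    A pixel is interior when every pixel within ``boundary_width``
    (Chebyshev) carries the same instance label; instance pixels near the
    outline — or near a different instance — become boundary. Interiors of
    distinct instances are therefore never 4-connected.
    """
    inst = np.asarray(instances)
    fg = inst > 0
    size = 2 * boundary_width + 1
    lo = ndimage.minimum_filter(inst, size=size, mode="constant", cval=0)
    hi = ndimage.maximum_filter(inst, size=size, mode="constant", cval=0)
    interior = fg & (lo == hi)
    out = np.zeros(inst.shape, dtype=np.uint8)
    out[fg] = 2
    out[interior] = 1
    return out


def extract_instances(mask: np.ndarray, min_area: int = 0) -> np.ndarray:
    """3-class mask -> instance label map.

    Connected components (4-connectivity) of the interior class seed the
    labels; each seed is expanded into the adjacent boundary pixels by
    watershed on the distance-to-seed transform. Components smaller than
    ``min_area`` are removed and labels renumbered 1..K.
    """
    mask = np.asarray(mask)
    interior = mask == 1
    fg = mask > 0
    seeds, n = ndimage.label(interior,
                             structure=np.array([[0, 1, 0],
                                                 [1, 1, 1],
                                                 [0, 1, 0]]))
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(~interior)
    labels = watershed(dist, markers=seeds, mask=fg)
    if min_area > 0:
        areas = np.bincount(labels.ravel())
        drop = np.flatnonzero(areas < min_area)
        labels[np.isin(labels, drop[drop > 0])] = 0
    # renumber 1..K
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return remap[labels]


def count_instances_in_tile(instances: np.ndarray, row: int, col: int,
                            tile_size: int) -> int:
    """Number of distinct instance labels intersecting a tile window."""
    window = instances[row:row + tile_size, col:col + tile_size]
    return int(len(np.unique(window[window > 0])))


# --- training ------------------------------------------------------------

@dataclass
class TrainSample:
    x: np.ndarray        # (2, T, T) float32: CD45, DAPI
    y: np.ndarray        # (T, T) uint8 class mask
    count: float


def make_training_samples(images: Sequence[Tuple[np.ndarray, np.ndarray]],
                          instance_maps: Sequence[np.ndarray],
                          tile_size: int, overlap: float = 0.2,
                          boundary_width: int = 2
                          ) -> List[List[TrainSample]]:
    """Tile (CD45, DAPI) FOVs plus instance maps into training samples.

    Returns one list of samples per FOV (so splits can be made by FOV);
    tiles with no labeled cells are dropped to reduce class imbalance.
    """
    per_fov: List[List[TrainSample]] = []
    for (cd45, dapi), inst in zip(images, instance_maps):
        classes = rasterize_labels(inst, boundary_width)
        stack = np.stack([cd45, dapi]).astype(np.float32)
        samples = []
        xt = tile_image(stack, tile_size, overlap)
        yt = tile_image(classes, tile_size, overlap)
        for tx, ty in zip(xt, yt):
            n = count_instances_in_tile(inst, tx.row, tx.col, tile_size)
            if n == 0:
                continue
            samples.append(TrainSample(tx.pixels, ty.pixels.astype(np.uint8),
                                       float(n)))
        per_fov.append(samples)
    return per_fov


def augment_sample(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                   noise_sd: float = 0.02, mean_shift_sd: float = 0.05
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Random 90-degree rotation, flips, additive noise and mean shift.

    Geometric transforms are applied identically to image and label mask;
    intensity perturbations touch the image only.
    """
    k = int(rng.integers(0, 4))
    if k:
        x = np.rot90(x, k, axes=(1, 2))
        y = np.rot90(y, k)
    if rng.random() < 0.5:
        x = x[:, ::-1]
        y = y[::-1]
    if rng.random() < 0.5:
        x = x[:, :, ::-1]
        y = y[:, ::-1]
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.ascontiguousarray(y)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, x.shape).astype(np.float32)
    if mean_shift_sd > 0:
        x = x + np.float32(rng.normal(0, mean_shift_sd))
    return x, y


@dataclass
class TrainHistory:
    epochs: List[Dict[str, float]] = field(default_factory=list)
    best_val_accuracy: float = 0.0
    best_epoch: int = -1


def _pixel_accuracy(model: MultiTaskUNet, samples: Sequence[TrainSample],
                    batch: int = 8) -> float:
    correct = total = 0
    for i in range(0, len(samples), batch):
        xs = np.stack([s.x for s in samples[i:i + batch]])
        ys = np.stack([s.y for s in samples[i:i + batch]])
        pred = model.predict_probs(xs).argmax(axis=1)
        correct += int((pred == ys).sum())
        total += ys.size
    return correct / max(total, 1)


def train(model: MultiTaskUNet,
          train_samples: Sequence[TrainSample],
          val_samples: Sequence[TrainSample],
          config: TrainConfig,
          weights: Optional[LossWeights] = None) -> TrainHistory:
    """Train the three-head network under the composite loss.

    The best checkpoint by validation pixel accuracy is restored into the
    model at the end. Raises if there are no non-empty training tiles.
    """
    if len(train_samples) == 0:
        raise ValueError("no non-empty training tiles")
    weights = weights or LossWeights()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate, l2=weights.beta)
    history = TrainHistory()
    best_weights = model.get_weights()
    order = np.arange(len(train_samples))

    for epoch in range(config.epochs):
        rng.shuffle(order)
        sums = {"total": 0.0, "ce": 0.0, "jacc": 0.0, "count": 0.0,
                "auto": 0.0, "reg": 0.0}
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xs, ys, ns = [], [], []
            for j in idx:
                s = train_samples[j]
                if config.augment:
                    x, y = augment_sample(s.x, s.y, rng,
                                          config.noise_sd,
                                          config.mean_shift_sd)
                else:
                    x, y = s.x, s.y
                xs.append(x)
                ys.append(y)
                ns.append(s.count)
            x = np.stack(xs)
            y = np.stack(ys)
            n = np.array(ns)

            out = model.forward(x)
            lce, ljacc, d_seg = seg_loss_grad(out["seg_logits"], y, weights)
            lcount, d_count = count_loss_grad(out["count"], n)
            lauto, d_recon = autoencode_loss_grad(out["recon"], x)
            lreg = model.l2_norm()
            loss = total_loss(lce, ljacc, lcount, lauto, lreg, weights)

            opt.zero_grad()
            model.backward(d_seg,
                           weights.lambda_c * d_count,
                           weights.lambda_a * d_recon)
            opt.step()

            sums["total"] += loss
            sums["ce"] += lce
            sums["jacc"] += ljacc
            sums["count"] += lcount
            sums["auto"] += lauto
            sums["reg"] += lreg
            n_batches += 1

        record = {k: v / n_batches for k, v in sums.items()}
        record["epoch"] = epoch
        if val_samples:
            acc = _pixel_accuracy(model, val_samples)
            record["val_accuracy"] = acc
            if acc > history.best_val_accuracy:
                history.best_val_accuracy = acc
                history.best_epoch = epoch
                best_weights = model.get_weights()
        history.epochs.append(record)

    if val_samples:
        model.set_weights(best_weights)
    return history


def train_with_restarts(arch: ArchConfig, train_samples, val_samples,
                        config: TrainConfig,
                        weights: Optional[LossWeights] = None
                        ) -> Tuple[MultiTaskUNet, TrainHistory]:
    """Train ``config.restarts`` independently seeded models and keep the
    best by validation pixel accuracy."""
    best_model, best_hist = None, None
    for r in range(max(1, config.restarts)):
        arch_r = ArchConfig(arch.in_channels, arch.base_filters, arch.depth,
                            arch.tile_size, seed=arch.seed + r)
        cfg_r = TrainConfig(**{**config.__dict__, "seed": config.seed + r})
        model = build_network(arch_r)
        hist = train(model, train_samples, val_samples, cfg_r, weights)
        if best_hist is None or \
           hist.best_val_accuracy > best_hist.best_val_accuracy:
            best_model, best_hist = model, hist
    return best_model, best_hist


# --- inference -----------------------------------------------------------

def predict_fov(model: MultiTaskUNet, cd45: np.ndarray, dapi: np.ndarray,
                tile_size: Optional[int] = None, overlap: float = 0.2,
                batch_size: int = 8) -> np.ndarray:
    """Predict the 3-class mask for a whole FOV.

    Tiles the two-channel stack, predicts softmax probabilities per tile,
    averages probabilities in overlap regions and takes the argmax.
    """
    cd45 = np.asarray(cd45, dtype=np.float32)
    dapi = np.asarray(dapi, dtype=np.float32)
    if cd45.shape != dapi.shape:
        raise ValueError(
            f"channel shape mismatch: {cd45.shape} vs {dapi.shape}")
    tile_size = tile_size or model.config.tile_size
    H, W = cd45.shape
    stack = np.stack([cd45, dapi])
    tiles = tile_image(stack, tile_size, overlap)
    prob_sum = np.zeros((3, H, W), dtype=np.float64)
    weight = np.zeros((H, W), dtype=np.float64)
    for i in range(0, len(tiles), batch_size):
        chunk = tiles[i:i + batch_size]
        x = np.stack([t.pixels for t in chunk])
        probs = model.predict_probs(x)
        for t, p in zip(chunk, probs):
            vh, vw = t.valid
            prob_sum[:, t.row:t.row + vh, t.col:t.col + vw] += p[:, :vh, :vw]
            weight[t.row:t.row + vh, t.col:t.col + vw] += 1.0
    probs = prob_sum / weight[None]
    return probs.argmax(axis=0).astype(np.uint8)


def per_class_f1(pred: np.ndarray, truth: np.ndarray,
                 n_classes: int = 3) -> np.ndarray:
    """Per-class F1 between two label maps (harmonic of precision/recall)."""
    out = np.zeros(n_classes)
    for k in range(n_classes):
        tp = int(((pred == k) & (truth == k)).sum())
        fp = int(((pred == k) & (truth != k)).sum())
        fn = int(((pred != k) & (truth == k)).sum())
        out[k] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return out
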