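"""Property-based validation runs on fully synthetic, ground-truthed data.

Each function builds its own dataset from the generator, runs one pipeline
capability end to end, and returns the measured quantities. These are the
computations behind the acceptance checks; they are ordinary library code
and can be used to re-validate the pipeline on any machine.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

from .losses import LossWeights, jaccard_loss, total_loss, \
    weighted_cross_entropy
from .network import ArchConfig, build_network
from .preprocess import preprocess_dataset
from .profiling import aggregate_cell_signals, profile_cells
from .registration import RegistrationConfig, align_cycle_set
from .segmentation import (TrainConfig, extract_instances,
                           make_training_samples, per_class_f1, predict_fov,
                           rasterize_labels, tile_image, train)
from .synth import SyntheticConfig, generate_dataset

EPS = 1e-7


# -- registration ---------------------------------------------------------

def registration_recovery(n_sets: int = 50, n_cycles: int = 7,
                          max_shift: int = 15, noise_sd: float = 30.0,
                          seed: int = 0) -> Dict:
    """Planted-shift recovery over many synthetic FOV sets.

    Returns the fraction of cycle shifts recovered within 2 px at full
    resolution and the worst error.
    """
    errors = []
    for s in range(n_sets):
        cfg = SyntheticConfig(n_cycles=n_cycles, n_fovs=1,
                              n_channels_per_cycle=2,
                              image_shape=(256, 256), n_cells=60,
                              max_shift=max_shift, noise_sd=noise_sd,
                              seed=seed * 1000 + s)
        ds, gt = generate_dataset(cfg)
        pre = preprocess_dataset(ds)
        result = align_cycle_set(pre, 0, RegistrationConfig(seed=seed + s))
        for j, (dy, dx) in enumerate(gt.shifts):
            entry = result.cycles[j]
            if entry.failed:
                errors.append(np.inf)
                continue
            got = entry.final_shift
            errors.append(max(abs(got[0] - dy), abs(got[1] - dx)))
    errors = np.asarray(errors)
    return {
        "fraction_within_2px": float((errors <= 2).mean()),
        "max_error_px": float(errors[np.isfinite(errors)].max()),
        "n_shifts": int(len(errors)),
    }


def registration_noise_free(n_sets: int = 10, seed: int = 0) -> Dict:
    """Noise-free recovery must be exact up to the downsampling grid.

    The default estimator works on the 2x-downsampled grid, so its error
    is bounded by one grid step (2 px at full resolution; plateau ties in
    the correlation can land on either neighbor of a half-step truth).
    With the optional full-resolution refinement pass the recovery is
    exact; both errors are reported.
    """
    errors, errors_ref = [], []
    for s in range(n_sets):
        cfg = SyntheticConfig(n_cycles=7, n_fovs=1, n_channels_per_cycle=2,
                              image_shape=(256, 256), n_cells=60,
                              max_shift=15, noise_sd=0.0,
                              seed=(seed + 77) * 1000 + s)
        ds, gt = generate_dataset(cfg)
        pre = preprocess_dataset(ds)
        for refine, bucket in ((False, errors), (True, errors_ref)):
            res = align_cycle_set(pre, 0,
                                  RegistrationConfig(seed=seed + s,
                                                     refine=refine))
            for j, (dy, dx) in enumerate(gt.shifts):
                e = res.cycles[j]
                if e.failed:
                    bucket.append(np.inf)
                    continue
                bucket.append(max(abs(e.final_shift[0] - dy),
                                  abs(e.final_shift[1] - dx)))
    return {"max_error_px": float(np.max(errors)),
            "max_error_refined_px": float(np.max(errors_ref)),
            "n_shifts": int(len(errors))}


# -- losses ---------------------------------------------------------------

def _loop_weighted_ce(probs, target, w: LossWeights) -> float:
    K, H, W = probs.shape
    total = 0.0
    for r in range(H):
        for c in range(W):
            y = int(target[r, c])
            weight = w.class_weights[y]
            if y == 2 and int(np.argmax(probs[:, r, c])) == 1:
                weight *= w.boundary_as_interior_multiplier
            total += weight * -math.log(max(probs[y, r, c], EPS))
    return total / (H * W)


def _loop_jaccard(probs, target) -> float:
    K, H, W = probs.shape
    losses = []
    for k in range(K):
        inter = sp = sy = 0.0
        for r in range(H):
            for c in range(W):
                y = 1.0 if target[r, c] == k else 0.0
                inter += probs[k, r, c] * y
                sp += probs[k, r, c]
                sy += y
        union = sp + sy - inter
        losses.append(1.0 - (inter + EPS) / (union + EPS))
    return float(np.mean(losses))


def loss_oracle_check(n_instances: int = 100, seed: int = 0) -> Dict:
    """Vectorized losses vs explicit per-pixel/per-class loops on random
    8x8x3 tensors, plus the composite sum at the default weights."""
    rng = np.random.default_rng(seed)
    w = LossWeights()
    max_ce = max_j = 0.0
    for _ in range(n_instances):
        z = rng.random((3, 8, 8))
        probs = z / z.sum(axis=0, keepdims=True)
        target = rng.integers(0, 3, (8, 8))
        max_ce = max(max_ce, abs(weighted_cross_entropy(probs, target, w)
                                 - _loop_weighted_ce(probs, target, w)))
        max_j = max(max_j, abs(jaccard_loss(probs, target)
                               - _loop_jaccard(probs, target)))
    composite = total_loss(1.0, 1.0, 1.0, 1.0, 1.0, w)
    return {
        "max_ce_diff": float(max_ce),
        "max_jaccard_diff": float(max_j),
        "composite_unit_components": float(composite),
        "n": n_instances,
    }


# -- segmentation ---------------------------------------------------------

def segmentation_learnability(seed: int = 0, epochs: int = 14,
                              n_fovs: int = 5) -> Dict:
    """Train the small network on synthetic tiles; score held-out FOVs.

    Uses the scaled training recipe (64 px tiles, depth-2 net with 8 base
    filters, rebalanced loss weights) on n_fovs-1 training FOVs and one
    held-out FOV. Returns held-out per-class F1 and the instance-count
    error of the full extraction chain against the planted count.
    """
    cfg = SyntheticConfig(n_cycles=2, n_fovs=n_fovs, n_channels_per_cycle=2,
                          image_shape=(512, 512), n_cells=150,
                          max_shift=0, touching_fraction=0.15,
                          seed=seed + 11)
    ds, gt = generate_dataset(cfg)
    pre = preprocess_dataset(ds)
    imgs = []
    for i in range(cfg.n_fovs):
        dapi = pre.pair(i, 0, 0).stain.pixels
        cd45 = pre.pair(i, 0, 1).stain.pixels
        imgs.append((np.asarray(cd45), np.asarray(dapi)))
    insts = [gt.instance_maps[i] for i in range(cfg.n_fovs)]
    per_fov = make_training_samples(imgs, insts, tile_size=64, overlap=0.2)

    train_s = [s for fov in per_fov[:-1] for s in fov]
    val_s = list(per_fov[-1])
    model = build_network(ArchConfig(in_channels=2, base_filters=8, depth=2,
                                     tile_size=64, seed=seed))
    weights = LossWeights(alpha=2.0, lambda_c=0.01, lambda_a=0.1, beta=1e-5)
    tconf = TrainConfig(tile_size=64, overlap_fraction=0.2, batch_size=8,
                        epochs=epochs, learning_rate=5e-4, seed=seed)
    history = train(model, train_s, val_s, tconf, weights)

    cd45, dapi = imgs[-1]
    pred = predict_fov(model, cd45, dapi, tile_size=64, overlap=0.2)
    truth = rasterize_labels(insts[-1])
    f1 = per_class_f1(pred, truth)
    n_pred = int(extract_instances(pred, min_area=10).max())
    n_true = int(insts[-1].max())
    return {
        "mean_f1": float(f1.mean()),
        "f1_background": float(f1[0]),
        "f1_interior": float(f1[1]),
        "f1_boundary": float(f1[2]),
        "count_error_pct": 100.0 * abs(n_pred - n_true) / n_true,
        "n_tiles": len(train_s) + len(val_s),
        "best_val_accuracy": history.best_val_accuracy,
    }


def roundtrip_instance_counts(n_layouts: int = 100, seed: int = 0) -> Dict:
    """rasterize -> extract round trip over random layouts, including
    touching pairs; returns the fraction with the count preserved."""
    rng = np.random.default_rng(seed)
    preserved = 0
    for _ in range(n_layouts):
        centers = []
        want = int(rng.integers(2, 10))
        attempts = 0
        while len(centers) < want and attempts < 500:
            attempts += 1
            r, c = rng.uniform(12, 84, 2)
            rad = rng.uniform(4, 8)
            touch = rng.random() < 0.3
            ok = True
            for r0, c0, rad0 in centers:
                d = np.hypot(r - r0, c - c0)
                lo = rad + rad0 - 1 if touch else rad + rad0 + 2
                if d < lo:
                    ok = False
                    break
            if ok:
                centers.append((r, c, rad))
        inst = np.zeros((96, 96), dtype=np.int32)
        rr, cc = np.mgrid[0:96, 0:96]
        for k, (r, c, rad) in enumerate(centers, start=1):
            inst[np.hypot(rr - r, cc - c) <= rad] = k
        out = extract_instances(rasterize_labels(inst, 2))
        preserved += int(out.max() == len(centers))
    return {"fraction_preserved": preserved / n_layouts, "n": n_layouts}


# -- profiling ------------------------------------------------------------

def profiling_fidelity(seed: int = 0, n_fovs: int = 5,
                       n_cells: int = 200) -> Dict:
    """Aggregation vs brute-force loops and planted-phenotype recovery
    with ground-truth masks (n_fovs * n_cells cells)."""
    cfg = SyntheticConfig(n_cycles=4, n_fovs=n_fovs, n_channels_per_cycle=4,
                          image_shape=(512, 512), n_cells=n_cells,
                          max_shift=0, seed=seed + 23)
    ds, gt = generate_dataset(cfg)
    quant = preprocess_dataset(ds, normalize=False)
    stacks = {
        i: {quant.marker(j, c): np.asarray(quant.pair(i, j, c).stain.pixels)
            for j in range(cfg.n_cycles)
            for c in range(cfg.n_channels_per_cycle)}
        for i in range(cfg.n_fovs)
    }

    # brute-force check of the mean aggregation on one FOV
    inst = gt.instance_maps[0]
    table0 = aggregate_cell_signals(inst, stacks[0])
    max_diff = 0.0
    marker = table0.markers[1]
    img = stacks[0][marker]
    for cid in range(1, int(inst.max()) + 1):
        expected = float(img[inst == cid].mean())
        got = float(table0.data.loc[cid - 1, marker])
        max_diff = max(max_diff, abs(got - expected))

    table = profile_cells(gt.instance_maps, stacks, mad_k=None,
                          threshold_method="otsu")
    import pandas as pd
    gtall = pd.concat([gt.cell_tables[i].assign(fov=i)
                       for i in range(cfg.n_fovs)])
    merged = table.data.assign(phenotype=table.phenotypes.values).merge(
        gtall, on=["fov", "cell_id"], suffixes=("", "_gt"))
    recovery = float((merged["phenotype"] == merged["phenotype_gt"]).mean())
    return {
        "max_mean_diff": max_diff,
        "phenotype_recovery_pct": 100.0 * recovery,
        "n_cells": int(len(merged)),
        "_table": table,
        "_truth": merged["phenotype_gt"].to_numpy(),
    }


# -- clustering -----------------------------------------------------------

def clustering_recovery(seed: int = 0, profiled=None) -> Dict:
    """ARI between HDBSCAN clusters and planted phenotypes on a profiled
    synthetic table (>= 3 well-separated phenotypes)."""
    from sklearn.metrics import adjusted_rand_score

    from .clustering import EmbeddingParams, cluster, embed

    if profiled is None:
        profiled = profiling_fidelity(seed=seed)
    table, truth = profiled["_table"], profiled["_truth"]
    emb = embed(table, EmbeddingParams(seed=seed))
    assign = cluster(emb)
    mask = assign.labels >= 0
    ari = adjusted_rand_score(truth[mask], assign.labels[mask])
    return {
        "ari": float(ari),
        "n_clusters": assign.n_clusters,
        "n_phenotypes": int(len(set(truth))),
        "n_cells": int(len(truth)),
    }


# -- tiling ---------------------------------------------------------------

def tiling_coverage(n_sizes: int = 100, seed: int = 0) -> Dict:
    """Stride arithmetic example plus full coverage on random sizes."""
    tiles = tile_image(np.zeros((540, 540)), 300, 0.2)
    offsets = sorted({(t.row, t.col) for t in tiles})
    stride_example_ok = offsets == [(0, 0), (0, 240), (240, 0), (240, 240)]

    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sizes):
        h, w = rng.integers(20, 800, 2)
        cover = np.zeros((h, w), dtype=bool)
        for t in tile_image(np.zeros((h, w)), 300, 0.2):
            vh, vw = t.valid
            cover[t.row:t.row + vh, t.col:t.col + vw] = True
        covered += int(cover.all())
    return {
        "n_tiles_540": len(tiles),
        "stride_example_ok": bool(stride_example_ok),
        "fraction_fully_covered": covered / n_sizes,
        "n_sizes": n_sizes,
    }
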