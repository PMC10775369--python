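"""Inter-cycle rigid translation estimation and correction.

Slides are removed and remounted between staining cycles, so every cycle is
offset from the reference by a small translation that is shared by all
fields of view of that cycle. One designated FOV per cycle is therefore
enough to estimate the cycle shift:

1. the C channel images of a cycle are collapsed by maximum projection
   (pooling "anchoring" cells visible in any channel) and downsampled 2x;
2. a foreground mask keeps only cell-sized connected components, making the
   correlation robust to debris; FOVs with too few objects are rejected;
3. over t trials, image and mask are randomly cropped (the same window for
   image and mask, and for reference and moving), and the translation is
   found as the peak of the masked normalized cross-correlation;
4. trial shifts far from the component-wise median are discarded and the
   mean of the survivors, scaled back to full resolution, is the cycle
   shift applied to every FOV of that cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform
from skimage.registration import phase_cross_correlation

from .dataset import ChannelImage, CyclicDataset


@dataclass
class RegistrationConfig:
    reference_cycle: int = 0
    downsample_factor: float = 0.5
    crop_factor: float = 0.75
    n_trials: int = 3
    outlier_distance: float = 4.0      # downsampled px, from trial median
    min_objects: int = 5
    size_band: Tuple[float, float] = (10.0, 2000.0)  # downsampled px^2
    refine: bool = False               # optional +-2 px full-res local search
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.crop_factor <= 1):
            raise ValueError("crop_factor must be in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        a_min, a_max = self.size_band
        if not a_min < a_max:
            raise ValueError("size_band must satisfy a_min < a_max")


@dataclass
class CycleShift:
    """Result for one cycle: per-trial shifts and the consensus shift."""

    trial_shifts: List[Tuple[float, float]] = field(default_factory=list)
    final_shift: Optional[Tuple[float, float]] = None
    failed: bool = False
    reason: str = ""
    objects_found: int = 0


@dataclass
class RegistrationResult:
    cycles: Dict[int, CycleShift]
    reference_cycle: int

    def shift(self, cycle: int) -> Tuple[float, float]:
        entry = self.cycles[cycle]
        if entry.failed or entry.final_shift is None:
            raise ValueError(f"cycle {cycle} failed: {entry.reason}")
        return entry.final_shift

    def to_json(self, path) -> None:
        raw = {
            str(j): {
                "dy": None if e.final_shift is None else e.final_shift[0],
                "dx": None if e.final_shift is None else e.final_shift[1],
                "failed": e.failed,
                "reason": e.reason,
                "objects_found": e.objects_found,
                "trials": [list(t) for t in e.trial_shifts],
            }
            for j, e in self.cycles.items()
        }
        raw["reference_cycle"] = self.reference_cycle
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegistrationResult":
        with open(path) as fh:
            raw = json.load(fh)
        ref = raw.pop("reference_cycle")
        cycles = {}
        for j, e in raw.items():
            cycles[int(j)] = CycleShift(
                trial_shifts=[tuple(t) for t in e["trials"]],
                final_shift=None if e["dy"] is None else (e["dy"], e["dx"]),
                failed=e["failed"], reason=e["reason"],
                objects_found=e["objects_found"])
        return cls(cycles=cycles, reference_cycle=ref)


def max_project(channel_images: Sequence[ChannelImage]) -> ChannelImage:
    """Pixel-wise maximum across channel images of one cycle."""
    if len(channel_images) == 0:
        raise ValueError("max_project needs at least one image")
    stack = np.stack([np.asarray(im.pixels, dtype=np.float64)
                      for im in channel_images])
    return ChannelImage(stack.max(axis=0),
                        normalized=all(im.normalized for im in channel_images))


def foreground_mask(img: ChannelImage,
                    size_band: Tuple[float, float]) -> Tuple[np.ndarray, int]:
    """Binary mask of cell-sized objects plus the object count.

    Otsu threshold, 3x3 morphological opening, then connected components
    filtered to areas within ``size_band``.
    """
    x = np.asarray(img.pixels, dtype=np.float64)
    if x.max() == x.min():
        return np.zeros(x.shape, bool), 0
    thresh = filters.threshold_otsu(x)
    binary = morphology.opening(x > thresh, footprint=np.ones((3, 3), bool))
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.zeros(x.shape, bool), 0
    areas = np.bincount(labels.ravel())[1:]
    a_min, a_max = size_band
    keep = np.flatnonzero((areas >= a_min) & (areas <= a_max)) + 1
    mask = np.isin(labels, keep)
    return mask, len(keep)


def _downsample(img: np.ndarray, factor: float) -> np.ndarray:
    return transform.rescale(img, factor, anti_aliasing=True,
                             preserve_range=True)


def _crop_window(shape, crop_factor, rng):
    h, w = shape
    ch = max(8, int(round(h * crop_factor)))
    cw = max(8, int(round(w * crop_factor)))
    ch, cw = min(ch, h), min(cw, w)
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    return slice(r0, r0 + ch), slice(c0, c0 + cw)


def estimate_shift(reference: ChannelImage, moving: ChannelImage,
                   ref_mask: np.ndarray, mov_mask: np.ndarray,
                   config: RegistrationConfig,
                   rng: Optional[np.random.Generator] = None) -> CycleShift:
    """Trial-averaged masked cross-correlation between two projections.

    Inputs are max-projected, normalized and already downsampled; the
    returned ``final_shift`` is expressed at full resolution (shifts are
    scaled back by 1/downsample_factor and rounded to integers). The shift
    convention is "moving = reference translated by final_shift".
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    entry = CycleShift()
    n_ref = _count_objects(ref_mask)
    n_mov = _count_objects(mov_mask)
    entry.objects_found = min(n_ref, n_mov)
    if entry.objects_found < config.min_objects:
        entry.failed, entry.reason = True, "low cellularity"
        return entry

    ref = np.asarray(reference.pixels, dtype=np.float64)
    mov = np.asarray(moving.pixels, dtype=np.float64)
    for _ in range(config.n_trials):
        rs, cs = _crop_window(ref.shape, config.crop_factor, rng)
        r_crop, m_crop = ref[rs, cs], mov[rs, cs]
        rm_crop, mm_crop = ref_mask[rs, cs], mov_mask[rs, cs]
        if rm_crop.sum() < 4 or mm_crop.sum() < 4:
            continue
        shift = phase_cross_correlation(
            r_crop, m_crop,
            reference_mask=rm_crop, moving_mask=mm_crop)[0]
        # skimage returns the shift registering moving onto reference,
        # i.e. minus the translation that produced the moving image
        entry.trial_shifts.append((-float(shift[0]), -float(shift[1])))

    if not entry.trial_shifts:
        entry.failed, entry.reason = True, "unstable correlation"
        return entry

    trials = np.array(entry.trial_shifts)
    med = np.median(trials, axis=0)
    keep = np.all(np.abs(trials - med) <= config.outlier_distance, axis=1)
    if not keep.any():
        entry.failed, entry.reason = True, "unstable correlation"
        return entry
    mean_shift = trials[keep].mean(axis=0) / config.downsample_factor
    entry.final_shift = (float(np.rint(mean_shift[0])),
                         float(np.rint(mean_shift[1])))
    return entry


def _count_objects(mask: np.ndarray) -> int:
    return int(ndimage.label(mask)[1])


def _refine_shift(ref: np.ndarray, mov: np.ndarray,
                  shift: Tuple[float, float], radius: int = 2
                  ) -> Tuple[float, float]:
    """Local +-radius search at full resolution around a candidate shift,
    maximizing the Pearson correlation on the overlap."""
    best, best_score = shift, -np.inf
    for dy in range(int(shift[0]) - radius, int(shift[0]) + radius + 1):
        for dx in range(int(shift[1]) - radius, int(shift[1]) + radius + 1):
            moved = apply_shift(ChannelImage(mov), (dy, dx)).pixels
            h, w = ref.shape
            rs = slice(max(0, -dy), min(h, h - dy)) if dy else slice(0, h)
            cs = slice(max(0, -dx), min(w, w - dx)) if dx else slice(0, w)
            a, b = ref[rs, cs].ravel(), moved[rs, cs].ravel()
            if a.std() == 0 or b.std() == 0:
                continue
            score = float(np.corrcoef(a, b)[0, 1])
            if score > best_score:
                best, best_score = (float(dy), float(dx)), score
    return best


def align_cycle_set(dataset: CyclicDataset, fov_for_alignment: int,
                    config: RegistrationConfig) -> RegistrationResult:
    """Estimate one shift per cycle from a single designated FOV.

    The dataset must be pre-processed (normalized stains). The reference
    cycle's shift is (0, 0) by convention; every other cycle's shift is
    measured against it and is later applied to all FOVs of that cycle.
    """
    rng = np.random.default_rng(config.seed)
    projections: Dict[int, ChannelImage] = {}
    masks: Dict[int, np.ndarray] = {}
    counts: Dict[int, int] = {}
    for j in range(dataset.n_cycles):
        chans = [dataset.pair(fov_for_alignment, j, c).stain
                 for c in range(dataset.n_channels)]
        proj = max_project(chans)
        small = ChannelImage(_downsample(proj.pixels, config.downsample_factor),
                             normalized=proj.normalized)
        projections[j] = small
        masks[j], counts[j] = foreground_mask(small, config.size_band)

    ref_j = config.reference_cycle
    cycles: Dict[int, CycleShift] = {}
    for j in range(dataset.n_cycles):
        if j == ref_j:
            entry = CycleShift(final_shift=(0.0, 0.0),
                               objects_found=counts[j])
            if counts[j] < config.min_objects:
                entry.failed, entry.reason = True, "low cellularity"
                entry.final_shift = None
            cycles[j] = entry
            continue
        entry = estimate_shift(projections[ref_j], projections[j],
                               masks[ref_j], masks[j], config, rng)
        if config.refine and not entry.failed:
            ref_full = max_project(
                [dataset.pair(fov_for_alignment, ref_j, c).stain
                 for c in range(dataset.n_channels)]).pixels
            mov_full = max_project(
                [dataset.pair(fov_for_alignment, j, c).stain
                 for c in range(dataset.n_channels)]).pixels
            entry.final_shift = _refine_shift(
                np.asarray(ref_full, float), np.asarray(mov_full, float),
                entry.final_shift)
        cycles[j] = entry
    return RegistrationResult(cycles=cycles, reference_cycle=ref_j)


def apply_shift(img: ChannelImage, shift: Tuple[float, float]) -> ChannelImage:
    """Translate an image by -shift so it lands on the reference frame.

    ``shift`` is the translation that produced the image from the reference
    scene; applying the inverse aligns it back. Vacated pixels are
    zero-filled; integer shifts use exact slicing.
    """
    dy, dx = shift
    x = np.asarray(img.pixels)
    if dy == 0 and dx == 0:
        return ChannelImage(x.copy(), normalized=img.normalized)
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.zeros_like(x, dtype=np.float64)
        dy, dx = int(dy), int(dx)
        h, w = x.shape
        src_r = slice(max(0, dy), min(h, h + dy))
        dst_r = slice(max(0, -dy), min(h, h - dy))
        src_c = slice(max(0, dx), min(w, w + dx))
        dst_c = slice(max(0, -dx), min(w, w - dx))
        out[dst_r, dst_c] = x[src_r, src_c]
    else:
        out = ndimage.shift(x.astype(np.float64), (-dy, -dx), order=1,
                            mode="constant", cval=0.0)
    return ChannelImage(out, normalized=img.normalized)


def align_dataset(dataset: CyclicDataset, result: RegistrationResult
                  ) -> Tuple[CyclicDataset, List[int]]:
    """Apply each cycle's consensus shift to every FOV of that cycle.

    Returns the aligned dataset and the list of failed cycles (whose
    images are kept unshifted and should be excluded downstream).
    """
    failed = [j for j, e in result.cycles.items() if e.failed]
    images = {}
    for (i, j, c), pair in dataset.images.items():
        if j in failed:
            images[(i, j, c)] = pair
            continue
        shifted = apply_shift(pair.stain, result.shift(j))
        images[(i, j, c)] = type(pair)(shifted, pair.quench)
    out = CyclicDataset(images=images, manifest=dict(dataset.manifest),
                        n_fovs=dataset.n_fovs, n_cycles=dataset.n_cycles,
                        n_channels=dataset.n_channels, sample=dataset.sample)
    return out, failed
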