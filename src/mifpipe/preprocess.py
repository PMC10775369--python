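"""Pixel-level pre-processing of raw cyclic images.

Three pointwise steps, applied in a fixed order to every stain image:

1. quench subtraction — the paired quenched-background image is subtracted
   pixel-by-pixel (clipped at zero), removing autofluorescence and residual
   signal from earlier cycles;
2. percentile normalization — intensities are rescaled to [0, 1] using the
   25th and 99th percentiles as lower and upper limits;
3. Gaussian denoising — a small Gaussian blur suppresses impulse noise.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy import ndimage

from .dataset import ChannelImage, CyclicDataset


class FlatImageWarning(UserWarning):
    """Percentile limits coincide; the normalized image is all zeros."""


def subtract_background(stain: ChannelImage, quench: ChannelImage) -> ChannelImage:
    """out = max(stain - quench, 0), pixel-wise."""
    if stain.shape != quench.shape:
        raise ValueError(
            f"shape mismatch: stain {stain.shape} vs quench {quench.shape}")
    a = stain.pixels.astype(np.float64)
    b = quench.pixels.astype(np.float64)
    return ChannelImage(np.maximum(a - b, 0.0))


def normalize_percentile(img: ChannelImage, p_low: float = 25.0,
                         p_high: float = 99.0) -> ChannelImage:
    """Rescale to [0, 1] between the p_low and p_high percentiles.

    A flat image (coincident percentiles) normalizes to all zeros and
    emits :class:`FlatImageWarning`.
    """
    x = img.pixels.astype(np.float64)
    if x.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(x, [p_low, p_high])
    if hi == lo:
        warnings.warn("flat image: percentile limits coincide; output is "
                      "all zeros", FlatImageWarning, stacklevel=2)
        return ChannelImage(np.zeros_like(x), normalized=True)
    out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return ChannelImage(out, normalized=True)


def gaussian_denoise(img: ChannelImage, sigma: float = 1.0) -> ChannelImage:
    """Gaussian blur with reflective borders; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ChannelImage(img.pixels.copy(), normalized=img.normalized)
    out = ndimage.gaussian_filter(img.pixels.astype(np.float64), sigma,
                                  mode="reflect")
    return ChannelImage(out, normalized=img.normalized)


def preprocess_pair(stain: ChannelImage, quench: ChannelImage,
                    p_low: float = 25.0, p_high: float = 99.0,
                    sigma: float = 1.0, normalize: bool = True
                    ) -> ChannelImage:
    """subtract -> normalize -> denoise, in that order.

    ``normalize=False`` skips the percentile step, leaving intensities on
    the background-subtracted absolute scale — the scale used for marker
    quantification, where percentile limits computed on a nearly-empty
    channel would destroy the on/off contrast.
    """
    out = subtract_background(stain, quench)
    if normalize:
        out = normalize_percentile(out, p_low=p_low, p_high=p_high)
    out = gaussian_denoise(out, sigma=sigma)
    return out


def preprocess_dataset(dataset: CyclicDataset, p_low: float = 25.0,
                       p_high: float = 99.0, sigma: float = 1.0,
                       normalize: bool = True) -> CyclicDataset:
    """Apply the fixed pointwise chain to every stain image.

    Returns a new dataset whose stain images are normalized floats in
    [0, 1] (or absolute background-subtracted intensities when
    ``normalize=False``); quench images are kept unchanged for provenance.
    """
    images = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FlatImageWarning)
        for key, pair in dataset.images.items():
            processed = preprocess_pair(pair.stain, pair.quench,
                                        p_low=p_low, p_high=p_high,
                                        sigma=sigma, normalize=normalize)
            images[key] = type(pair)(processed, pair.quench)
    return CyclicDataset(images=images, manifest=dict(dataset.manifest),
                         n_fovs=dataset.n_fovs, n_cycles=dataset.n_cycles,
                         n_channels=dataset.n_channels,
                         sample=dataset.sample)
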