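"""Training-time 2D augmentation with independently gated operations.

Six operations — center crop, scaling, horizontal flip, Gaussian
noise, Gaussian smoothing, contrast adjustment — are each applied
independently with probability ``gate_p`` (default 0.3), in that order
(geometric before intensity).  The output is always resized to the
model input resolution.  Magnitudes are mild by default and fully
configurable; augmentation is never applied at evaluation time (the
data loader asserts its mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = ["AugmentationConfig", "apply_augment"]


@dataclass
class AugmentationConfig:
    gate_p: float = 0.3
    crop_fraction: float = 0.85
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.02          # fraction of the image intensity range
    smooth_sigma: tuple[float, float] = (0.5, 1.0)   # pixels
    contrast_range: tuple[float, float] = (0.8, 1.2)
    output_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        if not 0.0 <= self.gate_p <= 1.0:
            raise ValueError("gate_p must be in [0, 1]")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in (0, 1]")
        for name, rng in (("scale_range", self.scale_range),
                          ("contrast_range", self.contrast_range)):
            if rng[1] < rng[0]:
                raise ValueError(f"{name} is empty: {rng}")


def _center_crop(img: np.ndarray, fraction: float) -> np.ndarray:
    h, w = img.shape
    ch, cw = max(1, int(round(h * fraction))), max(1, int(round(w * fraction)))
    top, left = (h - ch) // 2, (w - cw) // 2
    return img[top:top + ch, left:left + cw]


def _rescale(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the center; crop or zero-pad back to the input shape."""
    h, w = img.shape
    nh, nw = max(1, int(round(h * factor))), max(1, int(round(w * factor)))
    zoomed = resize(img, (nh, nw), order=1, mode="edge",
                    anti_aliasing=factor < 1.0, preserve_range=True)
    if factor >= 1.0:
        top, left = (nh - h) // 2, (nw - w) // 2
        return zoomed[top:top + h, left:left + w]
    out = np.zeros_like(img)
    top, left = (h - nh) // 2, (w - nw) // 2
    out[top:top + nh, left:left + nw] = zoomed
    return out


def apply_augment(image: np.ndarray, config: AugmentationConfig,
                  rng: np.random.Generator, return_gates: bool = False):
    """Apply the gated augmentation pipeline to one 2D image.

    Deterministic for a fixed generator state; the six gate draws are
    made unconditionally so that the random stream is identical
    whichever operations fire.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got {img.ndim}D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    gates = rng.random(6) < config.gate_p
    scale = rng.uniform(*config.scale_range)
    smooth = rng.uniform(*config.smooth_sigma)
    contrast = rng.uniform(*config.contrast_range)
    noise_field = rng.standard_normal(img.shape)

    if gates[0] and config.crop_fraction < 1.0:
        img = _center_crop(img, config.crop_fraction)
    if gates[1] and scale != 1.0:
        img = _rescale(img, scale)
    if gates[2]:
        img = img[:, ::-1]
    if gates[3] and config.noise_sigma > 0:
        span = float(np.ptp(img))
        sigma = config.noise_sigma * (span if span > 0 else 1.0)
        noise = noise_field if noise_field.shape == img.shape \
            else rng.standard_normal(img.shape)
        img = img + sigma * noise
    if gates[4] and smooth > 0:
        img = gaussian_filter(img, sigma=smooth)
    if gates[5]:
        mean = float(img.mean())
        img = (img - mean) * contrast + mean
    if img.shape != tuple(config.output_size):
        img = resize(img, config.output_size, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    out = np.ascontiguousarray(img, dtype=np.float32)
    if return_gates:
        return out, gates.copy()
    return out
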