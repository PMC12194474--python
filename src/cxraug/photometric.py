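"""Intensity augmentations under clinical bounds.

Brightness and contrast shifts are limited to ±10% by default; Gaussian
noise variance is sampled on the 8-bit intensity scale between 10.0 and
50.0 (σ ≈ 3.2–7.1 grey levels), the range a radiograph's acquisition noise
plausibly spans. Unit-scale images get the same noise via σ/255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import GrayImage


@dataclass(frozen=True)
class PhotometricParams:
    """Sampling bounds for intensity augmentation.

    brightness_limit δ: brightness offset drawn in [−δ, +δ] (unit scale).
    contrast_limit ε: contrast factor drawn as 1 + c, c in [−ε, +ε].
    noise_variance_range [ς_low, ς_high]: Gaussian noise variance on the
    8-bit scale.
    """

    brightness_limit: float = 0.10
    contrast_limit: float = 0.10
    noise_variance_range: tuple[float, float] = (10.0, 50.0)

    def __post_init__(self) -> None:
        if not 0 <= self.brightness_limit < 1:
            raise ValueError("brightness_limit must be in [0, 1)")
        if not 0 <= self.contrast_limit < 1:
            raise ValueError("contrast_limit must be in [0, 1)")
        lo, hi = self.noise_variance_range
        if lo < 0 or hi < lo:
            raise ValueError("noise_variance_range must be 0 <= low <= high")


def adjust_brightness_contrast(img: GrayImage, b: float, c: float) -> GrayImage:
    """Brightness offset ``b`` and contrast factor ``1 + c`` about mid-grey.

    ``out = clip((in − 0.5)·(1 + c) + 0.5 + b, 0, 1)``; the pivot 0.5 is a
    fixed point of pure contrast change, and ``b = c = 0`` is the identity.
    """
    if img.scale != "unit":
        raise ValueError("photometric augmentation expects a unit-scale image")
    out = (np.asarray(img.pixels, dtype=float) - 0.5) * (1.0 + c) + 0.5 + b
    return GrayImage(np.clip(out, 0.0, 1.0), scale="unit")


def add_gaussian_noise(
    img: GrayImage, variance_8bit: float, rng: np.random.Generator
) -> GrayImage:
    """Add zero-mean Gaussian noise with 8-bit-scale variance, then clip.

    On the unit scale the noise standard deviation is √(variance)/255.
    """
    if variance_8bit < 0:
        raise ValueError("noise variance must be nonnegative")
    if img.scale != "unit":
        raise ValueError("photometric augmentation expects a unit-scale image")
    if variance_8bit == 0:
        return img
    sigma = float(np.sqrt(variance_8bit)) / 255.0
    noisy = np.asarray(img.pixels, dtype=float) + rng.normal(0.0, sigma, img.pixels.shape)
    return GrayImage(np.clip(noisy, 0.0, 1.0), scale="unit")
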