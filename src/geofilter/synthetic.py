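"""Synthetic phantoms and noise injection.

The phantoms are simple scenes with known geometry — flat regions, a sharp
step, a linear ramp, a checkerboard, and band-limited texture — that stand in
for natural test photographs when exercising the filters: they contain the
two features edge-preserving smoothing must trade off (large homogeneous
areas and high-contrast boundaries) with an exactly known clean reference.

Noise models: zero-mean additive Gaussian (the benchmark default),
salt-and-pepper, and multiplicative speckle.  All randomness flows through
explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid

__all__ = ["NoiseSpec", "add_noise", "make_phantom", "PHANTOM_KINDS"]

PHANTOM_KINDS = ("piecewise_constant", "step", "ramp", "checkerboard", "texture")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: ``kind`` in {gaussian, salt_pepper, speckle}.

    ``sigma_n`` is the Gaussian standard deviation (0-255 scale) or the
    speckle relative amplitude; ``fraction`` the salt-and-pepper corruption
    fraction.  ``clip`` keeps the result in [0, 255] (the default, matching
    8-bit storage); disable it for analytic noise-statistics checks.
    """

    kind: str = "gaussian"
    sigma_n: float = 25.0
    fraction: float = 0.05
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "salt_pepper", "speckle"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must be in [0, 1]")


def add_noise(image: ImageGrid, spec: NoiseSpec) -> ImageGrid:
    """Corrupt ``image`` according to ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    vals = image.values
    if spec.kind == "gaussian":
        noisy = vals + rng.normal(0.0, spec.sigma_n, size=vals.shape) if spec.sigma_n > 0 else vals.copy()
    elif spec.kind == "speckle":
        noisy = vals * (1.0 + rng.normal(0.0, spec.sigma_n / 255.0, size=vals.shape))
    else:  # salt_pepper
        noisy = vals.copy()
        corrupt = rng.random(vals.shape[:2]) < spec.fraction
        salt = rng.random(vals.shape[:2]) < 0.5
        noisy[corrupt & salt] = 255.0
        noisy[corrupt & ~salt] = 0.0
    if spec.clip:
        noisy = np.clip(noisy, 0.0, 255.0)
    return ImageGrid(noisy)


def make_phantom(kind: str, dims: tuple[int, int] = (128, 128), seed: int = 0) -> ImageGrid:
    """Build a synthetic grayscale test scene of ``dims = (width, height)``.

    ``piecewise_constant`` has three flat regions whose level differences are
    at least 60 (edges dominate noise at sigma_n = 25); ``step`` is a 0/200
    vertical step; ``ramp`` runs 0 to 255 left to right; ``checkerboard``
    alternates 60/180 squares; ``texture`` is seeded band-limited noise
    around mid-grey.
    """
    width, height = dims
    if width < 2 or height < 2:
        raise ValueError(f"dims too small: {dims}")
    if kind == "piecewise_constant":
        img = np.full((height, width), 40.0)
        img[:, : width // 3] = 120.0
        yy, xx = np.mgrid[0:height, 0:width]
        r = min(width, height) // 5
        disk = (xx - 2 * width // 3) ** 2 + (yy - height // 2) ** 2 <= r * r
        img[disk] = 220.0
        return ImageGrid(img)
    if kind == "step":
        img = np.zeros((height, width))
        img[:, width // 2 :] = 200.0
        return ImageGrid(img)
    if kind == "ramp":
        col = 255.0 * np.arange(width) / (width - 1)
        return ImageGrid(np.tile(col, (height, 1)))
    if kind == "checkerboard":
        cell = max(4, min(width, height) // 8)
        yy, xx = np.mgrid[0:height, 0:width]
        board = ((xx // cell + yy // cell) % 2).astype(float)
        return ImageGrid(60.0 + 120.0 * board)
    if kind == "texture":
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=(height, width))
        band = ndimage.gaussian_filter(noise, sigma=3.0)
        band = band / (band.std() + 1e-12)
        return ImageGrid(np.clip(128.0 + 40.0 * band, 0.0, 255.0))
    raise ValueError(f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}")
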