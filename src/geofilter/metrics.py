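"""Image quality metrics: PSNR and SSIM.

PSNR is ``10 log10(V^2 / MSE)`` in decibels with ``V`` the dynamic range
(255 here); identical images return ``+inf``.  SSIM combines luminance,
contrast and structure terms,

    SSIM = (2 mu_x mu_y + c1)(2 cov_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2)),

with ``c1 = (k1 V)^2``, ``c2 = (k2 V)^2`` and defaults ``k1 = 0.01``,
``k2 = 0.03``.  Two modes are exposed: ``global`` evaluates the formula once
over the whole image; ``windowed`` is the conventional mean SSIM over an
11x11 Gaussian-weighted (sigma 1.5) sliding window, which is what the
benchmark reports use.  Colour pairs are compared on their luma channel for
SSIM, and with the MSE pooled over channels for PSNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid
from .io import to_grayscale

__all__ = ["MetricConfig", "psnr", "ssim"]


@dataclass(frozen=True)
class MetricConfig:
    """Dynamic range ``max_value`` and the SSIM constants ``k1``, ``k2``;
    ``ssim_mode`` selects ``"global"`` or ``"windowed"`` evaluation, with
    ``window``/``gaussian_sigma`` configuring the windowed mode."""

    max_value: float = 255.0
    k1: float = 0.01
    k2: float = 0.03
    ssim_mode: str = "global"
    window: int = 11
    gaussian_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.ssim_mode not in ("global", "windowed"):
            raise ValueError(f"ssim_mode must be 'global' or 'windowed', got {self.ssim_mode!r}")

    @property
    def c1(self) -> float:
        return (self.k1 * self.max_value) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.max_value) ** 2


def _check_shapes(reference: ImageGrid, test: ImageGrid) -> None:
    if reference.values.shape != test.values.shape:
        raise ValueError(
            f"shape mismatch: {reference.values.shape} vs {test.values.shape}"
        )


def psnr(reference: ImageGrid, test: ImageGrid, config: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio in dB (``+inf`` for identical images)."""
    config = config or MetricConfig()
    _check_shapes(reference, test)
    mse = float(np.mean((reference.values - test.values) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(config.max_value**2 / mse)


def ssim(reference: ImageGrid, test: ImageGrid, config: MetricConfig | None = None) -> float:
    """Structural similarity in [-1, 1]; 1 means identical."""
    config = config or MetricConfig()
    _check_shapes(reference, test)
    x = to_grayscale(reference).plane()
    y = to_grayscale(test).plane()
    if config.ssim_mode == "global":
        return _ssim_global(x, y, config)
    return _ssim_windowed(x, y, config)


def _ssim_global(x: np.ndarray, y: np.ndarray, config: MetricConfig) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + config.c1) * (2 * cov + config.c2)
        / ((mx * mx + my * my + config.c1) * (vx + vy + config.c2))
    )


def _ssim_windowed(x: np.ndarray, y: np.ndarray, config: MetricConfig) -> float:
    # Gaussian window of side `window`: sigma and truncation chosen so the
    # kernel radius is (window - 1) // 2
    radius = (config.window - 1) // 2
    sig = config.gaussian_sigma
    truncate = radius / sig

    def smooth(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma=sig, truncate=truncate)

    ux, uy = smooth(x), smooth(y)
    uxx, uyy, uxy = smooth(x * x), smooth(y * y), smooth(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    s = (
        (2 * ux * uy + config.c1) * (2 * vxy + config.c2)
        / ((ux * ux + uy * uy + config.c1) * (vx + vy + config.c2))
    )
    # drop the border band where the window hangs off the image
    core = s[radius:-radius, radius:-radius] if radius else s
    return float(core.mean())
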