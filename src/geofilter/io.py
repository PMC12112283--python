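"""Raster file input/output.

Supported formats: PNG, TIFF, PGM and PPM (both the plain-text ``P2``/``P3``
and binary ``P5``/``P6`` dialects are read; binary is written).  8-bit files
map to [0, 255] untouched; 16-bit files are linearly rescaled onto the same
scale.  Writing quantises with round-half-to-even to 8 bits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .grid import ImageGrid

__all__ = ["read_image", "write_image", "to_grayscale", "LUMA_WEIGHTS"]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma coefficients used for RGB -> grey conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".pgm", ".ppm"}


def read_image(path: str | Path) -> ImageGrid:
    """Read a raster file into an :class:`ImageGrid` on the 0-255 scale.

    Alpha channels are dropped (with a logged warning).  Unsupported bit
    depths raise ``ValueError``; unreadable files raise ``OSError`` naming
    the path.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises various types for bad files
        raise OSError(f"cannot read image file {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[2] in (2, 4):  # greyscale+alpha / RGBA
        logger.warning("dropping alpha channel while reading %s", path)
        arr = arr[:, :, :-1]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]

    if arr.dtype == np.uint8:
        values = arr.astype(np.float64)
    elif arr.dtype == np.uint16:
        values = arr.astype(np.float64) * (255.0 / 65535.0)
    else:
        raise ValueError(
            f"unsupported bit depth {arr.dtype} in {path}: expected 8- or 16-bit"
        )
    return ImageGrid(values)


def write_image(image: ImageGrid, path: str | Path) -> None:
    """Write ``image`` as an 8-bit raster; the format follows the extension.

    Values must already lie in [0, 255] — callers clip before writing.
    Quantisation uses round-half-to-even (numpy's ``rint``).
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported output format {path.suffix!r} for {path}")
    vals = image.values
    if vals.min() < 0.0 or vals.max() > 255.0:
        raise ValueError(
            f"values outside [0, 255] (range {vals.min():g}..{vals.max():g}); "
            "clip before writing"
        )
    data = np.rint(vals).astype(np.uint8)
    if data.shape[2] == 1:
        data = data[:, :, 0]
    iio.imwrite(path, data)


def to_grayscale(image: ImageGrid) -> ImageGrid:
    """Collapse RGB to a single luma channel (0.299 R + 0.587 G + 0.114 B).

    Single-channel input is returned unchanged.
    """
    if image.channels == 1:
        return image
    w = np.asarray(LUMA_WEIGHTS)
    return ImageGrid(image.values @ w)
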