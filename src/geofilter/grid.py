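"""In-memory image container.

Images are held as floating-point arrays on the 0-255 scale regardless of the
file bit depth.  Keeping the 8-bit scale (rather than normalising to [0, 1])
means signal differences share units with spatial steps of one pixel, which is
the convention all default filter parameters here assume: a signal weight
``alpha = 1`` makes a grey-level jump of 1 count as large as a one-pixel move,
and filtering extents ``sigma`` in the tens are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D raster with 1 (grey) or 3 (RGB) channels.

    Parameters
    ----------
    values : ndarray, shape (height, width, channels)
        Per-pixel intensities as float64 on the 0-255 scale.  All values must
        be finite.  Pixel coordinates are 0-based with ``u`` the column and
        ``v`` the row; the implicit spatial embedding is ``x(u, v) = u``,
        ``y(u, v) = v`` with unit pixel pitch.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D array, got shape {arr.shape}")
        if arr.shape[2] not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {arr.shape[2]}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"empty image: shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image values must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    def pixel(self, u: int, v: int) -> np.ndarray:
        """Channel vector at column ``u``, row ``v`` (bounds-checked)."""
        if not (0 <= u < self.width and 0 <= v < self.height):
            raise IndexError(f"pixel ({u}, {v}) outside {self.width}x{self.height} image")
        return self.values[v, u]

    def plane(self) -> np.ndarray:
        """The (height, width) array of a single-channel image."""
        if self.channels != 1:
            raise ValueError("plane() requires a single-channel image")
        return self.values[:, :, 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )
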