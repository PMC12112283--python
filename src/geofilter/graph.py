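"""The image as a Riemannian manifold: local window graphs with geodesic edge weights.

A grey or colour image is viewed as a surface embedded in R^(2+n): each pixel
``(u, v)`` maps to the point ``(u, v, r_1, ..., r_n)`` combining its spatial
coordinates (unit pixel pitch) with its ``n`` signal channels.  Distance on
this manifold accumulates both how far apart two pixels are on the grid and
how different their signals are; a single weight ``alpha`` scales the signal
term against the spatial one.

Geodesic distances are computed over small window-local graphs: the vertices
are the pixels of an odd ``w x w`` box clipped to the image, and the edges
connect 8-neighbours with weight

    sqrt(dS^2 + alpha^2 * ||dr||^2)

where ``dS`` is the spatial step (1 axial, sqrt(2) diagonal) and ``dr`` the
joint Euclidean signal difference across channels.  Paths never leave the
window box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid

__all__ = [
    "MetricParams",
    "WindowSpec",
    "WindowGraph",
    "NEIGHBOR_OFFSETS",
    "embed",
    "edge_weight",
    "build_window_graph",
]

#: The 8-connectivity stencil as (du, dv) offsets, axial steps first.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
)


@dataclass(frozen=True)
class MetricParams:
    """Manifold metric configuration.

    ``alpha`` weights signal differences against spatial distance; 0 reduces
    the metric to pure grid distance.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")


@dataclass(frozen=True)
class WindowSpec:
    """An odd ``size x size`` window centred on pixel ``center = (u0, v0)``."""

    center: tuple[int, int]
    size: int

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {self.size}")

    @property
    def half_width(self) -> int:
        return self.size // 2


@dataclass
class WindowGraph:
    """Undirected weighted graph over a window's in-bounds pixels.

    Vertices are absolute pixel coordinates ``(u, v)``; ``adjacency`` maps
    each vertex to its ``(neighbour, weight)`` list.  Weights are symmetric
    and bounded below by the spatial step length.
    """

    vertices: list[tuple[int, int]]
    adjacency: dict[tuple[int, int], list[tuple[tuple[int, int], float]]]
    center: tuple[int, int] = field(default=(0, 0))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


def embed(image: ImageGrid, u: int, v: int) -> np.ndarray:
    """Map pixel ``(u, v)`` onto the manifold point ``(u, v, r_1, ..., r_n)``."""
    signal = image.pixel(u, v)  # bounds-checked
    return np.concatenate(([float(u), float(v)], signal))


def edge_weight(
    image: ImageGrid,
    p: tuple[int, int],
    q: tuple[int, int],
    params: MetricParams,
) -> float:
    """Geodesic edge weight between 8-neighbouring pixels ``p`` and ``q``."""
    du, dv = q[0] - p[0], q[1] - p[1]
    if (du, dv) not in NEIGHBOR_OFFSETS:
        raise ValueError(f"{p} and {q} are not 8-neighbours")
    dr = image.pixel(*q) - image.pixel(*p)
    ds2 = float(du * du + dv * dv)  # 1 axial, 2 diagonal
    return math.sqrt(ds2 + params.alpha**2 * float(np.dot(dr, dr)))


def build_window_graph(
    image: ImageGrid, window: WindowSpec, params: MetricParams
) -> WindowGraph:
    """Build the 8-connected graph over the window's in-bounds pixels.

    Windows overlapping the image border are clipped; no padding or
    reflection is applied.  The result is always connected (king-move
    adjacency on a solid rectangle).
    """
    u0, v0 = window.center
    if not (0 <= u0 < image.width and 0 <= v0 < image.height):
        raise ValueError(f"window center {window.center} outside image")
    h = window.half_width
    umin, umax = max(0, u0 - h), min(image.width - 1, u0 + h)
    vmin, vmax = max(0, v0 - h), min(image.height - 1, v0 + h)

    vertices = [(u, v) for v in range(vmin, vmax + 1) for u in range(umin, umax + 1)]
    in_window = set(vertices)
    adjacency: dict[tuple[int, int], list[tuple[tuple[int, int], float]]] = {
        p: [] for p in vertices
    }
    for p in vertices:
        for du, dv in NEIGHBOR_OFFSETS:
            q = (p[0] + du, p[1] + dv)
            if q in in_window:
                adjacency[p].append((q, edge_weight(image, p, q, params)))
    return WindowGraph(vertices=vertices, adjacency=adjacency, center=(u0, v0))
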