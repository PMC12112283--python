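"""Single-source minimal geodesic paths within a window graph.

Two production engines are provided plus one test oracle:

* :func:`dijkstra_window` — binary-heap Dijkstra, the exact scalar reference.
* :func:`wave_propagation_window` — synchronous ring-ordered relaxation
  (concentric Chebyshev "waves" around the source, swept to a fixed point),
  the engine whose data access pattern parallelises; on a CPU it is iterated
  until exact, so its distances match Dijkstra to double precision.
* :func:`brute_force_geodesic` — exhaustive minimum over simple paths, for
  tiny graphs only; used to validate the other two.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

__all__ = [
    "DistanceMap",
    "dijkstra_window",
    "wave_propagation_window",
    "brute_force_geodesic",
]

Vertex = tuple[int, int]


@dataclass
class DistanceMap:
    """Geodesic distances from a source vertex over a window graph.

    ``distances[v]`` is the length of the shortest path from ``source`` to
    ``v``; ``predecessors[v]`` the previous vertex on one such path (``None``
    at the source); ``visited[v]`` whether the vertex was finalised.
    ``n_waves`` is filled by the wave engine only: the number of ring
    relaxations that changed at least one distance.
    """

    source: Vertex
    distances: dict[Vertex, float]
    predecessors: dict[Vertex, Vertex | None]
    visited: dict[Vertex, bool] = field(default_factory=dict)
    n_waves: int | None = None

    def path_to(self, v: Vertex) -> list[Vertex]:
        """The vertex chain from ``source`` to ``v`` along predecessors."""
        chain = [v]
        while self.predecessors[chain[-1]] is not None:
            chain.append(self.predecessors[chain[-1]])  # type: ignore[arg-type]
        return chain[::-1]


def _check_source(graph, source: Vertex) -> None:
    if source not in graph.adjacency:
        raise ValueError(f"source {source} is not a vertex of the graph")


def dijkstra_window(graph, source: Vertex) -> DistanceMap:
    """Exact single-source shortest paths with a binary heap.

    Stale heap entries are skipped via the visited flag (no decrease-key).
    Ties are broken by insertion order; distances are tie-independent.
    """
    _check_source(graph, source)
    dist: dict[Vertex, float] = {v: math.inf for v in graph.adjacency}
    pred: dict[Vertex, Vertex | None] = {v: None for v in graph.adjacency}
    visited: dict[Vertex, bool] = {v: False for v in graph.adjacency}
    dist[source] = 0.0

    counter = itertools.count()
    heap: list[tuple[float, int, Vertex]] = [(0.0, next(counter), source)]
    while heap:
        d, _, p = heapq.heappop(heap)
        if visited[p]:
            continue
        visited[p] = True
        for q, w in graph.adjacency[p]:
            if visited[q]:
                continue
            nd = d + w
            if nd < dist[q]:
                dist[q] = nd
                pred[q] = p
                heapq.heappush(heap, (nd, next(counter), q))
    return DistanceMap(source=source, distances=dist, predecessors=pred, visited=visited)


def wave_propagation_window(graph, source: Vertex) -> DistanceMap:
    """Ring-ordered synchronous relaxation ("wave propagation").

    Vertices are grouped into concentric rings of Chebyshev radius 0, 1, 2,
    ... around the source.  A sweep processes the rings in order; every
    vertex of the current ring relaxes all its 8-neighbours.  Sweeps repeat
    until no distance changes, so the fixed point equals the true shortest
    path distances.  ``n_waves`` counts the ring relaxations that updated at
    least one distance — on a uniform window one sweep suffices, giving
    ``half_width + 1`` waves.
    """
    _check_source(graph, source)
    dist: dict[Vertex, float] = {v: math.inf for v in graph.adjacency}
    pred: dict[Vertex, Vertex | None] = {v: None for v in graph.adjacency}
    dist[source] = 0.0

    max_radius = max(
        max(abs(v[0] - source[0]), abs(v[1] - source[1])) for v in graph.adjacency
    )
    rings: list[list[Vertex]] = [[] for _ in range(max_radius + 1)]
    for v in graph.adjacency:
        rings[max(abs(v[0] - source[0]), abs(v[1] - source[1]))].append(v)

    n_waves = 0
    while True:
        changed_any = False
        waves_this_sweep = 0
        for ring in rings:
            if any(math.isfinite(dist[p]) for p in ring):
                waves_this_sweep += 1
            for p in ring:
                dp = dist[p]
                if not math.isfinite(dp):
                    continue
                for q, w in graph.adjacency[p]:
                    nd = dp + w
                    if nd < dist[q]:
                        dist[q] = nd
                        pred[q] = p
                        changed_any = True
        if not changed_any:
            break  # verification sweep: no work, not counted
        n_waves += waves_this_sweep
    n_waves = max(n_waves, 1)  # a 1-vertex graph still spends one wave on the source
    visited = {v: math.isfinite(dist[v]) for v in graph.adjacency}
    return DistanceMap(
        source=source, distances=dist, predecessors=pred, visited=visited, n_waves=n_waves
    )


def brute_force_geodesic(graph, source: Vertex, max_vertices: int = 25) -> DistanceMap:
    """Exact minimum over all simple paths, by exhaustive depth-first search.

    A path is abandoned as soon as its running length is no better than the
    best simple path already found to its endpoint, which discards only
    provably non-minimal paths.  Guarded to ``max_vertices`` vertices
    (default 25, a 5x5 window) because the search cost grows combinatorially.
    """
    _check_source(graph, source)
    if len(graph.adjacency) > max_vertices:
        raise ValueError(
            f"brute-force oracle refused: {len(graph.adjacency)} vertices "
            f"(limit {max_vertices})"
        )
    best: dict[Vertex, float] = {v: math.inf for v in graph.adjacency}
    pred: dict[Vertex, Vertex | None] = {v: None for v in graph.adjacency}
    best[source] = 0.0
    on_path: set[Vertex] = {source}

    def extend(p: Vertex, length: float) -> None:
        for q, w in graph.adjacency[p]:
            if q in on_path:
                continue
            nd = length + w
            # with nonnegative weights a prefix that cannot improve best[q]
            # cannot lie on a minimal simple path to any vertex beyond q
            if nd >= best[q]:
                continue
            best[q] = nd
            pred[q] = p
            on_path.add(q)
            extend(q, nd)
            on_path.discard(q)

    extend(source, 0.0)
    visited = {v: True for v in graph.adjacency}
    return DistanceMap(source=source, distances=best, predecessors=pred, visited=visited)
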