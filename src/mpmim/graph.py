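"""Pruned KNN graph over embedding space.

The graph is the communication path for message passing: each spot is a
node, linked to its ``k_num`` nearest neighbors by embedding-space Euclidean
distance, symmetrized by union, then pruned per node so that unusually far
neighbors (beyond mean + 1 sd of that node's neighbor distances) are dropped.
Exact O(n^2) search is used throughout — the method targets slide-scale
inputs (<= a few thousand spots).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .types import EmbeddingMatrix

__all__ = ["NeighborGraph", "knn_graph", "prune_graph", "adjacency", "write_edge_list"]


@dataclass(frozen=True)
class NeighborGraph:
    """Per-node neighbor indices with embedding-space distances.

    ``neighbors[i]`` and ``distances[i]`` are parallel arrays sorted by
    (distance, index); self-loops never appear.  When ``undirected`` is set,
    ``j in neighbors[i]``  iff  ``i in neighbors[j]``.
    """

    n: int
    neighbors: tuple[np.ndarray, ...]
    distances: tuple[np.ndarray, ...]
    undirected: bool = True

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n or len(self.distances) != self.n:
            raise ValueError("neighbor lists do not match node count")
        for i, (nb, d) in enumerate(zip(self.neighbors, self.distances)):
            if len(nb) != len(d):
                raise ValueError(f"node {i}: index/distance length mismatch")
            if len(nb) == 0:
                raise ValueError(f"node {i} has no neighbors")
            if np.any(nb == i):
                raise ValueError(f"node {i} has a self-loop")
            if not np.all(np.isfinite(d)) or np.any(d < 0):
                raise ValueError(f"node {i}: invalid distances")

    def degree(self, i: int) -> int:
        return len(self.neighbors[i])


def _sorted_lists(dist: np.ndarray, nbr_sets: list[set[int]]) -> NeighborGraph:
    """Assemble a graph from neighbor sets, ordering each list by
    (distance, index) for determinism."""
    n = dist.shape[0]
    neighbors, distances = [], []
    for i in range(n):
        idx = np.fromiter(sorted(nbr_sets[i]), dtype=np.int64)
        d = dist[i, idx]
        order = np.lexsort((idx, d))  # distance first, index breaks ties
        neighbors.append(idx[order])
        distances.append(d[order])
    return NeighborGraph(n, tuple(neighbors), tuple(distances), undirected=True)


def pairwise_distances(emb: EmbeddingMatrix) -> np.ndarray:
    return cdist(emb.values, emb.values)


def knn_graph(
    emb: EmbeddingMatrix, k_num: int, dist: np.ndarray | None = None
) -> NeighborGraph:
    """Undirected KNN graph on embedding-space Euclidean distance.

    Each node selects its ``k_num`` nearest other nodes (ties broken by
    ascending index); the edge set is the union of the directed selections.
    A precomputed pairwise distance matrix may be supplied.
    """
    n = emb.n_spots
    if not 1 <= k_num <= n - 1:
        raise ValueError(f"k_num must be in [1, {n - 1}], got {k_num}")
    dist = pairwise_distances(emb) if dist is None else np.array(dist, dtype=float)
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distances -> ascending-index tie break
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_num]
    np.fill_diagonal(dist, 0.0)
    nbr_sets: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in order[i]:
            nbr_sets[i].add(int(j))
            nbr_sets[int(j)].add(i)  # union symmetrization
    return _sorted_lists(dist, nbr_sets)


def prune_graph(g: NeighborGraph, dist: np.ndarray | None = None) -> NeighborGraph:
    """Drop per-node outlier neighbors, keeping the graph connected enough
    for message passing.

    For each node, neighbors farther than mean + 1 sd of that node's
    neighbor distances are removed; the single nearest neighbor is always
    retained.  Symmetry is re-established by union, so a neighbor survives
    if either endpoint keeps the edge.  Applied exactly once.
    """
    kept: list[set[int]] = [set() for _ in range(g.n)]
    for i in range(g.n):
        d = g.distances[i]
        nb = g.neighbors[i]
        threshold = d.mean() + d.std()  # population sd
        keep = d <= threshold
        keep[0] = True  # nearest neighbor always retained
        for j in nb[keep]:
            kept[i].add(int(j))
    # union symmetrization
    sym: list[set[int]] = [set() for _ in range(g.n)]
    for i in range(g.n):
        for j in kept[i]:
            sym[i].add(j)
            sym[j].add(i)
    dist_lookup = _distance_lookup(g) if dist is None else None
    neighbors, distances = [], []
    for i in range(g.n):
        idx = np.fromiter(sorted(sym[i]), dtype=np.int64)
        if dist is not None:
            d = dist[i, idx]
        else:
            d = np.array([dist_lookup[(min(i, j), max(i, j))] for j in idx])
        order = np.lexsort((idx, d))
        neighbors.append(idx[order])
        distances.append(d[order])
    return NeighborGraph(g.n, tuple(neighbors), tuple(distances), undirected=True)


def _distance_lookup(g: NeighborGraph) -> dict[tuple[int, int], float]:
    lut: dict[tuple[int, int], float] = {}
    for i in range(g.n):
        for j, d in zip(g.neighbors[i], g.distances[i]):
            lut[(min(i, int(j)), max(i, int(j)))] = float(d)
    return lut


def adjacency(g: NeighborGraph, weighted: bool = False) -> np.ndarray:
    """Dense symmetric adjacency with zero diagonal; binary by default,
    edge distances when ``weighted``."""
    a = np.zeros((g.n, g.n))
    for i in range(g.n):
        a[i, g.neighbors[i]] = g.distances[i] if weighted else 1.0
    return a


def write_edge_list(g: NeighborGraph, path: str | Path) -> None:
    """Inspection output: one ``i<TAB>j<TAB>distance`` line per undirected edge."""
    lines = ["i\tj\tdistance"]
    for i in range(g.n):
        for j, d in zip(g.neighbors[i], g.distances[i]):
            if i < j:
                lines.append(f"{i}\t{j}\t{d:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
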