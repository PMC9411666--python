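"""Embedding transformation by stacked neighborhood aggregation.

Each layer replaces a spot's feature vector by a convex combination of its
graph neighbors' vectors.  With the "distance" type, aggregation weights are
a softmax of the raw embedding-space Euclidean distances, so *farther*
neighbors get *larger* weight: the transform deliberately injects
long-distance dependency that short-range graph convolutions underweight.
The "basic" type is a plain graph convolution with uniform neighbor weights.
No nonlinearities, biases, or trainable parameters — the transform is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .graph import NeighborGraph, knn_graph, pairwise_distances, prune_graph
from .types import EmbeddingMatrix, MpMimConfig

__all__ = [
    "AggregationWeights",
    "distance_weights",
    "uniform_weights",
    "pass_layer",
    "transform",
]


@dataclass(frozen=True)
class AggregationWeights:
    """Per-node convex weights over its graph neighborhood.

    ``matrix`` is the row-stochastic n x n aggregation operator: row i holds
    alpha_ij on node i's neighbors (and on i itself when self-inclusion is
    enabled), zero elsewhere.
    """

    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        rs = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("aggregation weights must row-sum to 1")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("aggregation weights must be non-negative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _build(g: NeighborGraph, include_self: bool, weight_fn) -> AggregationWeights:
    rows, cols, data = [], [], []
    for i in range(g.n):
        nb = g.neighbors[i].astype(np.int64)
        d = g.distances[i].astype(float)
        if include_self:
            nb = np.append(nb, i)
            d = np.append(d, 0.0)
        alpha = weight_fn(d)
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
        data.extend(alpha.tolist())
    m = sparse.csr_matrix((data, (rows, cols)), shape=(g.n, g.n))
    return AggregationWeights(m)


def distance_weights(
    g: NeighborGraph, include_self: bool = False, overflow_guard: float = 700.0
) -> AggregationWeights:
    """Softmax-of-distance weights: alpha_ij = exp(d_ij) / sum_k exp(d_ik).

    Raw distances feed the softmax (no max-subtraction), so any node whose
    largest neighbor distance exceeds ``overflow_guard`` (the double-precision
    exp overflow bound) falls back to uniform weights for that node.
    """

    def weight_fn(d: np.ndarray) -> np.ndarray:
        if d.max() > overflow_guard:
            return np.full(len(d), 1.0 / len(d))
        e = np.exp(d)
        return e / e.sum()

    return _build(g, include_self, weight_fn)


def uniform_weights(g: NeighborGraph, include_self: bool = False) -> AggregationWeights:
    """Basic graph convolution: every neighbor gets weight 1/|N_i|."""
    return _build(g, include_self, lambda d: np.full(len(d), 1.0 / len(d)))


def pass_layer(emb: EmbeddingMatrix, w: AggregationWeights) -> EmbeddingMatrix:
    """One aggregation layer: h'_i = sum_{j in N_i} alpha_ij h_j, applied to
    every dimension independently."""
    if w.n != emb.n_spots:
        raise ValueError(f"weights are {w.n} x {w.n} but embedding has {emb.n_spots} spots")
    return emb.with_values(w.matrix @ emb.values)


def transform(emb: EmbeddingMatrix, cfg: MpMimConfig) -> EmbeddingMatrix:
    """Full message-passing transform.

    The pruned KNN graph and the aggregation weights are computed once from
    the *original* embedding and held fixed while ``l_num`` layers are
    applied; ``l_num = 0`` returns the input unchanged.
    """
    if cfg.l_num == 0:
        return emb
    if cfg.k_num >= emb.n_spots:
        raise ValueError(
            f"k_num={cfg.k_num} must be smaller than the number of spots ({emb.n_spots})"
        )
    dist = pairwise_distances(emb)
    g = knn_graph(emb, cfg.k_num, dist=dist)
    if cfg.prune:
        g = prune_graph(g, dist=dist)
    if cfg.mp_type == "distance":
        w = distance_weights(g, cfg.include_self, cfg.overflow_guard)
    else:
        w = uniform_weights(g, cfg.include_self)
    out = emb
    for _ in range(cfg.l_num):
        out = pass_layer(out, w)
    return out
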