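"""Global spatial autocorrelation of embedding dimensions.

Global Moran's I for a variable x over n spots with binary spatial weights
w_ij (zero diagonal, S0 = sum_ij w_ij):

    I = n * sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S0 * sum_i (x_i - xbar)^2)

Geary's C:

    C = (n - 1) * sum_ij w_ij (x_i - x_j)^2 / (2 * S0 * sum_i (x_i - xbar)^2)

C lies in [0, 2]; it is reported as 1 - C so that +1 means perfect positive
autocorrelation, matching Moran's I sign convention.  Weights are binary and
normalized only through S0 (no row standardization).  An embedding is scored
per dimension and reduced across dimensions by max (default), mean or min
filtering; constant dimensions are undefined and excluded from the reduction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist, pdist, squareform

from .types import EmbeddingMatrix, FilterType, SpotCoordinates

logger = logging.getLogger("mpmim")

__all__ = [
    "SpatialWeightMatrix",
    "AutocorrelationScore",
    "radius_weights",
    "knn_weights",
    "morans_i",
    "gearys_c",
    "score_embedding",
    "auto_radius",
]


@dataclass(frozen=True)
class SpatialWeightMatrix:
    """Binary spot x spot spatial weights with zero diagonal."""

    w: sparse.csr_matrix
    scheme: str
    parameter: float

    def __post_init__(self) -> None:
        if self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if self.w.diagonal().any():
            raise ValueError("weight matrix must have zero diagonal")
        if self.w.nnz == 0:
            raise ValueError("weight matrix has no neighbors (S0 = 0)")
        if (self.w != self.w.T).nnz:
            raise ValueError("weight matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def auto_radius(coords: SpotCoordinates) -> float:
    """Smallest radius giving every spot at least one neighbor: the maximum
    over spots of the nearest-neighbor distance."""
    d = squareform(pdist(coords.xy))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


def radius_weights(
    coords: SpotCoordinates, radius: float | str = "auto"
) -> SpatialWeightMatrix:
    """w_ij = 1 iff 0 < d_ij <= radius (spatial Euclidean distance)."""
    if isinstance(radius, str):
        if radius != "auto":
            raise ValueError("radius must be a positive number or 'auto'")
        radius = auto_radius(coords)
    elif radius <= 0:
        raise ValueError("radius must be > 0")
    d = squareform(pdist(coords.xy))
    w = (d <= radius)
    np.fill_diagonal(w, False)
    if not w.any():
        raise ValueError(
            f"radius {radius} leaves every spot without neighbors; use radius='auto'"
        )
    return SpatialWeightMatrix(sparse.csr_matrix(w.astype(float)), "radius", float(radius))


def knn_weights(coords: SpotCoordinates, k: int) -> SpatialWeightMatrix:
    """Binary weights from spatial k-nearest neighbors, symmetrized by union;
    distance ties broken by ascending spot index."""
    n = coords.n_spots
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d = cdist(coords.xy, coords.xy)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    w = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k)
    w[rows, order.ravel()] = 1.0
    w = np.maximum(w, w.T)  # union symmetrization
    return SpatialWeightMatrix(sparse.csr_matrix(w), "knn", float(k))


def _centered(x: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float).ravel()
    z = x - x.mean()
    return z, float(z @ z)


def morans_i(x: np.ndarray, w: SpatialWeightMatrix) -> float:
    """Global Moran's I of one embedding dimension; NaN for a constant
    (zero-variance) input, for which the statistic is undefined."""
    z, ss = _centered(x)
    if len(z) != w.n:
        raise ValueError(f"x has {len(z)} values but weights are {w.n} x {w.n}")
    if ss == 0.0:
        return math.nan
    return float(w.n * (z @ (w.w @ z)) / (w.s0 * ss))


def gearys_c(x: np.ndarray, w: SpatialWeightMatrix) -> float:
    """1 - Geary's C of one embedding dimension (so +1 = perfect positive,
    -1 = perfect negative, 0 = none); NaN for constant input."""
    z, ss = _centered(x)
    if len(z) != w.n:
        raise ValueError(f"x has {len(z)} values but weights are {w.n} x {w.n}")
    if ss == 0.0:
        return math.nan
    # sum_ij w_ij (x_i - x_j)^2 = 2 * (sum_i deg_i x_i^2 - x' W x) for symmetric binary W
    deg = np.asarray(w.w.sum(axis=1)).ravel()
    sq = 2.0 * (deg @ (z**2) - z @ (w.w @ z))
    gc = (w.n - 1) * sq / (2.0 * w.s0 * ss)
    return float(1.0 - gc)


_STATISTICS = {"moran": morans_i, "geary": gearys_c}
_FILTERS = {"max": np.max, "avg": np.mean, "min": np.min}


@dataclass(frozen=True)
class AutocorrelationScore:
    """Per-dimension statistics and their reduction across dimensions.

    ``per_dimension`` holds one value per embedding dimension (NaN where the
    dimension is constant); ``value`` is the max/avg/min over the defined
    dimensions.
    """

    embedding_name: str
    per_dimension: tuple[float, ...]
    value: float
    statistic: str
    filter_type: FilterType

    @property
    def n_undefined(self) -> int:
        return int(np.sum(np.isnan(self.per_dimension)))


def score_embedding(
    emb: EmbeddingMatrix,
    w: SpatialWeightMatrix,
    statistic: str = "moran",
    filter_type: FilterType = "max",
) -> AutocorrelationScore:
    """Score every dimension of an embedding and reduce across dimensions.

    Zero-variance dimensions are excluded from the reduction (a constant
    dimension carries no spatial signal; scoring it 0 would distort the avg
    and min filters).  All dimensions constant is an error.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if filter_type not in _FILTERS:
        raise ValueError(f"unknown filter_type {filter_type!r}")
    stat = _STATISTICS[statistic]
    per_dim = tuple(stat(emb.values[:, j], w) for j in range(emb.n_dims))
    defined = [v for v in per_dim if not math.isnan(v)]
    if not defined:
        raise ValueError(
            f"embedding {emb.name!r}: every dimension has zero variance"
        )
    if len(defined) < len(per_dim):
        logger.warning(
            "embedding %s: %d zero-variance dimension(s) excluded from %s filtering",
            emb.name, len(per_dim) - len(defined), filter_type,
        )
    return AutocorrelationScore(
        embedding_name=emb.name,
        per_dimension=per_dim,
        value=float(_FILTERS[filter_type](defined)),
        statistic=statistic,
        filter_type=filter_type,
    )
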