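"""Domain types shared by all stages.

The spot order of an :class:`EmbeddingMatrix` is canonical: coordinates,
labels, graphs and weight matrices are all indexed by it after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "SpotCoordinates",
    "LabelVector",
    "MpMimConfig",
]


def _check_ids(spot_ids: Sequence[str]) -> list[str]:
    ids = [str(s) for s in spot_ids]
    seen: set[str] = set()
    dups = []
    for s in ids:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise ValueError(f"duplicate spot ids: {sorted(set(dups))}")
    return ids


@dataclass(frozen=True)
class EmbeddingMatrix:
    """A spots x dimensions matrix of latent values with spot identifiers.

    Parameters
    ----------
    spot_ids
        Ordered unique spot identifiers; row order defines the index ``i``
        used by every graph and statistic operation downstream.
    values
        Numeric matrix of shape ``(n_spots, n_dims)``; all entries finite.
    name
        Provenance label, e.g. a hyperparameter tag of the model that
        produced the embedding.
    """

    spot_ids: tuple[str, ...]
    values: np.ndarray
    name: str = "embedding"

    def __post_init__(self) -> None:
        ids = _check_ids(self.spot_ids)
        object.__setattr__(self, "spot_ids", tuple(ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"embedding values must be 2-D, got ndim={vals.ndim}")
        if vals.shape[0] != len(ids):
            raise ValueError(
                f"{vals.shape[0]} rows but {len(ids)} spot ids"
            )
        if vals.shape[0] < 2:
            raise ValueError("an embedding needs at least 2 spots")
        if vals.shape[1] < 1:
            raise ValueError("an embedding needs at least 1 dimension")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))
            raise ValueError(f"non-finite embedding values at (row, col) {bad[:5].tolist()}")
        object.__setattr__(self, "values", vals)

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "EmbeddingMatrix":
        return EmbeddingMatrix(self.spot_ids, values, name if name is not None else self.name)


@dataclass(frozen=True)
class SpotCoordinates:
    """Per-spot 2-D spatial positions (array or pixel units, consistent
    within a dataset)."""

    spot_ids: tuple[str, ...]
    xy: np.ndarray

    def __post_init__(self) -> None:
        ids = _check_ids(self.spot_ids)
        object.__setattr__(self, "spot_ids", tuple(ids))
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError(
                f"coordinates must be n x 2 (2-D spatial data only), got shape {xy.shape}"
            )
        if xy.shape[0] != len(ids):
            raise ValueError(f"{xy.shape[0]} coordinate rows but {len(ids)} spot ids")
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "xy", xy)

    @property
    def n_spots(self) -> int:
        return self.xy.shape[0]


@dataclass(frozen=True)
class LabelVector:
    """Categorical ground-truth annotation per spot (e.g. cortical layer)."""

    spot_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = _check_ids(self.spot_ids)
        object.__setattr__(self, "spot_ids", tuple(ids))
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != len(ids):
            raise ValueError(f"{len(labels)} labels but {len(ids)} spot ids")
        object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


MpType = Literal["distance", "basic"]
WeightType = Literal["radius", "knn"]
FilterType = Literal["max", "avg", "min"]


@dataclass(frozen=True)
class MpMimConfig:
    """Hyperparameters for the full transform-and-score pipeline.

    ``k_num`` and ``l_num`` control the message passing (KNN-graph size and
    number of stacked aggregation layers); large values of both are the
    recommended operating point.  ``mp_type`` selects distance-softmax
    aggregation weights ("distance") or uniform weights ("basic").
    ``weight_type``/``radius``/``knn_w`` configure the spatial weight matrix
    used by the autocorrelation statistics, and ``filter_type`` the reduction
    across embedding dimensions.
    """

    k_num: int = 90
    l_num: int = 15
    mp_type: MpType = "distance"
    weight_type: WeightType = "radius"
    filter_type: FilterType = "max"
    radius: float | str = "auto"
    knn_w: int = 6
    seed: int = 0
    include_self: bool = False
    prune: bool = True
    overflow_guard: float = 700.0

    def __post_init__(self) -> None:
        if self.k_num < 1:
            raise ValueError("k_num must be a positive integer")
        if self.l_num < 0:
            raise ValueError("l_num must be non-negative")
        if self.mp_type not in ("distance", "basic"):
            raise ValueError(f"unknown mp_type {self.mp_type!r}")
        if self.weight_type not in ("radius", "knn"):
            raise ValueError(f"unknown weight_type {self.weight_type!r}")
        if self.filter_type not in ("max", "avg", "min"):
            raise ValueError(f"unknown filter_type {self.filter_type!r}")
        if isinstance(self.radius, str):
            if self.radius != "auto":
                raise ValueError("radius must be a positive number or 'auto'")
        elif self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.knn_w < 1:
            raise ValueError("knn_w must be a positive integer")

    def replace(self, **kw) -> "MpMimConfig":
        return replace(self, **kw)
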