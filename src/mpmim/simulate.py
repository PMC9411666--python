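"""Synthetic Visium-like lattices and embedding suites.

Fixtures emulate the *structure* of spatial transcriptomics inputs — spots
on a (hexagonally offset) lattice, low-dimensional embeddings whose spatial
smoothness is controlled, and contiguous annotated domains — without
simulating gene-expression counts: the tool's contract starts at embedding
space.

Each embedding dimension is a spatially smooth field plus i.i.d. Gaussian
noise.  The smooth field assigns one N(0,1) value per spatial domain block
and averages it through a Gaussian distance kernel of length-scale
``smoothness``, then standardizes to unit sd, so ``noise_sd`` directly sets
the noise-to-signal ratio and hence the expected Moran's I.  ``smoothness=0``
yields pure i.i.d. noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .types import EmbeddingMatrix, LabelVector, SpotCoordinates

__all__ = ["FixtureSpec", "make_lattice", "make_embedding", "make_suite", "make_labels"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; deterministic given ``seed``."""

    lattice: str = "hex"
    rows: int = 20
    cols: int = 20
    n_dims: int = 3
    smoothness: float = 3.0
    noise_sd: float = 0.0
    n_domains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice not in ("square", "hex"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.rows * self.cols < 4:
            raise ValueError("lattice needs at least 4 spots")
        if self.smoothness < 0 or self.noise_sd < 0:
            raise ValueError("smoothness and noise_sd must be >= 0")
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")


def make_lattice(spec: FixtureSpec) -> SpotCoordinates:
    """Square lattice = integer grid; hex lattice = Visium-like offset rows
    with unit nearest-neighbor spacing."""
    r, c = np.divmod(np.arange(spec.rows * spec.cols), spec.cols)
    if spec.lattice == "square":
        x = c.astype(float)
        y = r.astype(float)
    else:
        # odd rows shifted by half a spacing; row pitch sqrt(3)/2 keeps
        # nearest-neighbor distance exactly 1
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
    ids = tuple(f"spot{ri}_{ci}" for ri, ci in zip(r, c))
    return SpotCoordinates(ids, np.column_stack([x, y]).astype(float))


def _domain_of(coords: SpotCoordinates, n_domains: int) -> np.ndarray:
    """Partition the lattice into contiguous vertical bands by x coordinate."""
    x = coords.xy[:, 0]
    edges = np.quantile(x, np.linspace(0, 1, n_domains + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def make_labels(coords: SpotCoordinates, spec: FixtureSpec) -> LabelVector:
    """Ground-truth annotation: ``n_domains`` contiguous spatial blocks."""
    dom = _domain_of(coords, spec.n_domains)
    return LabelVector(coords.spot_ids, tuple(f"domain{d}" for d in dom))


def make_embedding(
    coords: SpotCoordinates, spec: FixtureSpec, name: str = "synthetic"
) -> EmbeddingMatrix:
    """Smooth spatial field + i.i.d. noise, one draw per dimension."""
    rng = np.random.default_rng(spec.seed)
    n = coords.n_spots
    values = np.empty((n, spec.n_dims))
    dom = _domain_of(coords, spec.n_domains)
    if spec.smoothness > 0:
        d2 = cdist(coords.xy, coords.xy, "sqeuclidean")
        kernel = np.exp(-d2 / (2.0 * spec.smoothness**2))
        kernel /= kernel.sum(axis=1, keepdims=True)
    for j in range(spec.n_dims):
        if spec.smoothness > 0:
            block_values = rng.standard_normal(spec.n_domains)
            field = kernel @ block_values[dom]
            sd = field.std()
            if sd > 0:
                field = field / sd
        else:
            field = np.zeros(n)
        values[:, j] = field + spec.noise_sd * rng.standard_normal(n)
    return EmbeddingMatrix(coords.spot_ids, values, name)


def make_suite(
    coords: SpotCoordinates,
    m: int = 8,
    spec: FixtureSpec | None = None,
    noise_range: tuple[float, float] = (3.0, 0.0),
) -> tuple[list[EmbeddingMatrix], list[str], LabelVector]:
    """A suite of ``m`` embeddings with a known quality ordering.

    Noise sd is interpolated from ``noise_range[0]`` (worst) down to
    ``noise_range[1]`` (best) at fixed smoothness; embeddings are named
    e01..e<m> in construction order.  Returns (embeddings, true quality
    order best-first, domain labels).
    """
    spec = spec or FixtureSpec()
    if m < 2:
        raise ValueError("a suite needs at least 2 embeddings")
    noise_levels = np.linspace(noise_range[0], noise_range[1], m)
    # one shared signal field: suite members emulate embeddings of the SAME
    # sample produced at different hyperparameters, so the underlying tissue
    # signal is common and only the noise level (quality) varies
    signal = make_embedding(coords, replace(spec, noise_sd=0.0)).values
    embs = []
    for i, noise_sd in enumerate(noise_levels):
        rng = np.random.default_rng((spec.seed * 1000 + i + 1) % (2**31 - 1))
        values = signal + float(noise_sd) * rng.standard_normal(signal.shape)
        embs.append(EmbeddingMatrix(coords.spot_ids, values, f"e{i + 1:02d}"))
    # quality increases as noise decreases: last-constructed is best
    true_order = [e.name for e in reversed(embs)]
    labels = make_labels(coords, spec)
    return embs, true_order, labels
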