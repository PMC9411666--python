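import numpy as np
import pytest

from mpmim import EmbeddingMatrix, FixtureSpec, SpotCoordinates, make_lattice


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_4x4():
    """4x4 unit-spaced square lattice (16 spots)."""
    return make_lattice(FixtureSpec(lattice="square", rows=4, cols=4))


@pytest.fixture
def square_10x10():
    return make_lattice(FixtureSpec(lattice="square", rows=10, cols=10))


@pytest.fixture
def checkerboard_4x4(square_4x4):
    """+/-1 checkerboard field on the 4x4 lattice, paired with its coords."""
    xy = square_4x4.xy
    x = np.where((xy[:, 0] + xy[:, 1]) % 2 == 0, 1.0, -1.0)
    return square_4x4, x


def random_embedding(rng, n, d, name="emb"):
    return EmbeddingMatrix(
        tuple(f"s{i}" for i in range(n)), rng.standard_normal((n, d)), name
    )


def random_coords(rng, n):
    return SpotCoordinates(
        tuple(f"s{i}" for i in range(n)), rng.uniform(0, 10, size=(n, 2))
    )


# ---------------------------------------------------------------------------
# independent oracles (no matrix algebra / no sklearn), used across test files
# ---------------------------------------------------------------------------

def moran_brute(x, w):
    """Double-loop Moran's I on a dense binary weight matrix."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    den = float(sum((xi - xbar) ** 2 for xi in x))
    return n * num / (s0 * den)


def geary_brute(x, w):
    """Double-loop raw Geary's C on a dense binary weight matrix."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - x[j]) ** 2
            s0 += w[i, j]
    den = float(sum((xi - xbar) ** 2 for xi in x))
    return (n - 1) * num / (2.0 * s0 * den)


def ari_pairs(a, b):
    """ARI by enumerating all spot pairs and counting agreements."""
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0:
        return 1.0
    return num / den
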