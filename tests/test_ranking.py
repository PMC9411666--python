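import numpy as np
import pytest

from mpmim import (
    EmbeddingMatrix,
    FixtureSpec,
    LabelVector,
    MpMimConfig,
    ari,
    baseline_per_dimension,
    evaluate_ranking,
    ground_truth_ranking,
    make_lattice,
    make_suite,
    rank_embeddings,
    ranking_from_order,
    spearman,
    top_k_report,
)

from conftest import ari_pairs, random_embedding


def labels_of(ids, values):
    return LabelVector(tuple(ids), tuple(str(v) for v in values))


# ---------------------------------------------------------------- ARI


def test_ari_identical_and_relabelled():
    ids = [f"s{i}" for i in range(6)]
    a = labels_of(ids, [1, 1, 2, 2, 3, 3])
    assert ari(a, a) == pytest.approx(1.0)
    b = labels_of(ids, ["x", "x", "y", "y", "z", "z"])  # permuted label names
    assert ari(a, b) == pytest.approx(1.0)


def test_ari_crossed_partition_matches_pair_enumeration():
    ids = ["s0", "s1", "s2", "s3"]
    a = labels_of(ids, [1, 1, 2, 2])
    b = labels_of(ids, [1, 2, 1, 2])
    expected = ari_pairs([1, 1, 2, 2], [1, 2, 1, 2])
    assert ari(a, b) == pytest.approx(expected)
    assert expected == pytest.approx(-0.5)


def test_ari_matches_pair_oracle_random(rng):
    for _ in range(30):
        n = int(rng.integers(4, 30))
        ids = [f"s{i}" for i in range(n)]
        la = rng.integers(0, 4, n)
        lb = rng.integers(0, 3, n)
        assert ari(labels_of(ids, la), labels_of(ids, lb)) == pytest.approx(
            ari_pairs(la, lb), abs=1e-10
        )


def test_ari_alignment_by_id_not_position():
    a = LabelVector(("s0", "s1"), ("x", "y"))
    b = LabelVector(("s1", "s0"), ("y", "x"))
    assert ari(a, b) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="spot sets"):
        ari(a, LabelVector(("q0", "q1"), ("x", "y")))


# ------------------------------------------------------------ Spearman


def test_spearman_examples():
    a = {f"e{i}": r for i, r in enumerate([1, 2, 3, 4, 5])}
    assert spearman(a, a).rho == pytest.approx(1.0)

    b = {f"e{i}": r for i, r in enumerate([1, 3, 2, 5, 4])}
    res = spearman(a, b)
    # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
    assert res.rho == pytest.approx(0.8)
    assert res.clamped_rho == pytest.approx(0.8)

    rev = {f"e{i}": r for i, r in enumerate([5, 4, 3, 2, 1])}
    res = spearman(a, rev)
    assert res.rho == pytest.approx(-1.0)
    assert res.clamped_rho == 0.0


def test_spearman_matches_rank_formula(rng):
    """rho equals Pearson on tie-averaged ranks computed explicitly."""
    from scipy.stats import rankdata

    for _ in range(10):
        m = int(rng.integers(4, 15))
        names = [f"e{i}" for i in range(m)]
        a = dict(zip(names, rng.integers(0, 6, m).astype(float)))  # ties likely
        b = dict(zip(names, rng.standard_normal(m)))
        ra = rankdata([a[n] for n in names])
        rb = rankdata([b[n] for n in names])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert spearman(a, b).rho == pytest.approx(expected, abs=1e-12)


def test_spearman_input_validation():
    a = {"x": 1.0, "y": 2.0, "z": 3.0}
    with pytest.raises(ValueError, match="item sets"):
        spearman(a, {"x": 1.0, "y": 2.0, "w": 3.0})
    with pytest.raises(ValueError, match="3 items"):
        spearman({"x": 1.0, "y": 2.0}, {"x": 1.0, "y": 2.0})


# ------------------------------------------------------- rank_embeddings


@pytest.fixture
def small_suite():
    spec = FixtureSpec(lattice="hex", rows=8, cols=8, n_dims=3, seed=5)
    coords = make_lattice(spec)
    embs, true_order, labels = make_suite(coords, m=5, spec=spec)
    return coords, embs, true_order, labels


def test_rank_identical_embeddings_tie_by_name(small_suite):
    coords, embs, _, _ = small_suite
    twin = EmbeddingMatrix(embs[0].spot_ids, embs[0].values, "zz_copy")
    first = EmbeddingMatrix(embs[0].spot_ids, embs[0].values, "aa_copy")
    cfg = MpMimConfig(k_num=10, l_num=2)
    result = rank_embeddings([twin, first], coords, cfg)
    assert result.table["score"].nunique() == 1
    assert result.names_by_rank == ["aa_copy", "zz_copy"]


def test_rank_gradient_beats_noise_without_transform(rng):
    coords = make_lattice(FixtureSpec(lattice="square", rows=8, cols=8))
    ids = coords.spot_ids
    gradient = EmbeddingMatrix(ids, coords.xy[:, [0]], "gradient")
    noise = EmbeddingMatrix(ids, rng.standard_normal((64, 1)), "noise")
    cfg = MpMimConfig(l_num=0, weight_type="radius", radius=1.0)
    result = rank_embeddings([noise, gradient], coords, cfg)
    assert result.names_by_rank[0] == "gradient"


def test_rank_order_invariance(small_suite):
    coords, embs, _, _ = small_suite
    cfg = MpMimConfig(k_num=10, l_num=3)
    fwd = rank_embeddings(embs, coords, cfg)
    rev = rank_embeddings(list(reversed(embs)), coords, cfg)
    assert fwd.names_by_rank == rev.names_by_rank
    np.testing.assert_allclose(fwd.table["score"], rev.table["score"])


def test_rank_recovers_construction_order(small_suite):
    coords, embs, true_order, _ = small_suite
    cfg = MpMimConfig(k_num=30, l_num=5)
    result = rank_embeddings(embs, coords, cfg)
    truth = ranking_from_order(true_order)
    rho = spearman(
        dict(zip(result.table["name"], result.table["rank"].astype(float))),
        dict(zip(truth.table["name"], truth.table["rank"].astype(float))),
    ).rho
    assert rho == pytest.approx(1.0)


def test_rank_inconsistent_spot_sets_errors(small_suite, rng):
    coords, embs, _, _ = small_suite
    alien = random_embedding(rng, 10, 3, name="alien")
    with pytest.raises(ValueError, match="alien"):
        rank_embeddings(embs + [alien], coords)


# ------------------------------------------------- ground-truth ranking


def test_ground_truth_one_hot_is_rank_one(rng):
    n, k = 40, 4
    ids = tuple(f"s{i}" for i in range(n))
    classes = np.repeat(np.arange(k), n // k)
    one_hot = np.eye(k)[classes]
    perfect = EmbeddingMatrix(ids, one_hot.astype(float), "perfect")
    noise = EmbeddingMatrix(ids, rng.standard_normal((n, k)), "noise")
    labels = labels_of(ids, classes)
    result = ground_truth_ranking([noise, perfect], labels, seed=0)
    assert result.names_by_rank[0] == "perfect"
    assert result.score_of("perfect") == pytest.approx(1.0)
    assert result.names_by_rank[-1] == "noise"


def test_ground_truth_deterministic_given_seed(small_suite):
    _, embs, _, labels = small_suite
    r1 = ground_truth_ranking(embs, labels, seed=11)
    r2 = ground_truth_ranking(embs, labels, seed=11)
    assert r1.names_by_rank == r2.names_by_rank
    np.testing.assert_array_equal(r1.table["ari"], r2.table["ari"])


def test_ground_truth_missing_labels_errors(small_suite):
    _, embs, _, labels = small_suite
    short = LabelVector(labels.spot_ids[:-1], labels.labels[:-1])
    with pytest.raises(ValueError, match="lack labels"):
        ground_truth_ranking(embs, short)


# ------------------------------------------------------ top-k & baseline


def test_top_k_full_always_contains_best(small_suite):
    coords, embs, _, labels = small_suite
    predicted = rank_embeddings(embs, coords, MpMimConfig(k_num=10, l_num=3))
    truth = ground_truth_ranking(embs, labels, seed=0)
    top, flag = top_k_report(predicted, truth, k=len(embs))
    assert flag
    assert len(top) == len(embs)
    with pytest.raises(ValueError, match="k must be"):
        top_k_report(predicted, truth, k=len(embs) + 1)


def test_evaluate_ranking_report(small_suite):
    coords, embs, _, labels = small_suite
    predicted = rank_embeddings(embs, coords, MpMimConfig(k_num=20, l_num=5))
    truth = ground_truth_ranking(embs, labels, seed=0)
    report = evaluate_ranking(predicted, truth, k=3)
    assert -1.0 <= report.spearman.rho <= 1.0
    assert report.spearman.clamped_rho == max(report.spearman.rho, 0.0)
    assert set(report.per_embedding["name"]) == {e.name for e in embs}
    assert sorted(report.per_embedding["predicted_rank"]) == list(
        range(1, len(embs) + 1)
    )


def test_baseline_single_dimension_suite(small_suite, rng):
    """With 1-D embeddings the per-dimension baseline is exactly the
    untransformed filtered score ranking."""
    coords, _, _, _ = small_suite
    ids = coords.spot_ids
    embs = [
        EmbeddingMatrix(ids, rng.standard_normal((len(ids), 1)), f"b{i}")
        for i in range(4)
    ]
    cfg = MpMimConfig(l_num=0)
    truth = ranking_from_order([e.name for e in embs])
    base = baseline_per_dimension(embs, coords, truth, "moran", cfg)
    assert len(base) == 1
    untransformed = rank_embeddings(embs, coords, cfg)
    sp = spearman(
        dict(zip(untransformed.table["name"], untransformed.table["rank"].astype(float))),
        dict(zip(truth.table["name"], truth.table["rank"].astype(float))),
    )
    assert base["rho"].iloc[0] == pytest.approx(sp.rho)


def test_baseline_geary_uses_sign_compatible_transform(small_suite):
    coords, embs, true_order, _ = small_suite
    truth = ranking_from_order(true_order)
    moran_base = baseline_per_dimension(embs, coords, truth, "moran")
    geary_base = baseline_per_dimension(embs, coords, truth, "geary")
    # 1-GC orients like Moran's I: on a noise-graded suite both baselines
    # correlate positively with the construction order
    assert moran_base["rho"].max() > 0
    assert geary_base["rho"].max() > 0
    assert moran_base["is_best"].sum() >= 1
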