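import numpy as np
import pytest

from enhancerkit.encoders import FeatureMatrix
from enhancerkit.selection import (
    RANKING_METHODS,
    FeatureRanking,
    aggregate_pagerank,
    cv_accuracy,
    default_evaluator,
    forward_select,
    ga_select,
    iterative_reduce,
    rank_features,
    reduce_once,
)


def make_matrix(X, prefix="f"):
    n, p = X.shape
    return FeatureMatrix(
        [f"{prefix}{j:03d}" for j in range(p)], X, [f"r{i:03d}" for i in range(n)]
    )


@pytest.fixture
def planted(rng):
    """One perfectly label-aligned feature among 19 noise features."""
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 20))
    X[:, 7] = y + rng.normal(scale=0.05, size=n)
    return make_matrix(X), y


@pytest.mark.parametrize("method", ["anova", "chi2", "mic", "mrmr"])
def test_perfect_feature_ranked_first(planted, method):
    matrix, y = planted
    ranking = rank_features(matrix, y, method, seed=0)
    assert ranking.ordered[0] == "f007"


@pytest.mark.parametrize("method", RANKING_METHODS)
def test_constant_feature_ranked_last_or_tied(planted, method):
    matrix, y = planted
    X = matrix.values.copy()
    X[:, 3] = 1.0  # constant
    m = make_matrix(X)
    ranking = rank_features(m, y, method, seed=0)
    pos = ranking.ordered.index("f003")
    # tied-last allowed: score no greater than any feature after it
    assert all(ranking.scores[pos] <= s + 1e-9 for s in ranking.scores[:pos])
    assert ranking.scores[pos] <= min(ranking.scores) + 1e-9


def test_single_class_labels_error(planted):
    matrix, _ = planted
    with pytest.raises(ValueError, match="single class"):
        rank_features(matrix, np.zeros(matrix.shape[0], dtype=int), "anova")


def test_anova_f_matches_hand_computed_value():
    """Textbook one-way F for two groups of 10 with means 0 and 1."""
    g0 = np.array([-0.5, 0.5] * 5)  # mean 0
    g1 = g0 + 1.0  # mean 1
    x = np.concatenate([g0, g1])
    y = np.repeat([0, 1], 10)
    # brute-force sums of squares
    grand = x.mean()
    ssb = 10 * (g0.mean() - grand) ** 2 + 10 * (g1.mean() - grand) ** 2
    ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    f_expected = (ssb / 1) / (ssw / 18)
    matrix = make_matrix(x[:, None])
    ranking = rank_features(matrix, y, "anova")
    assert ranking.scores[0] == pytest.approx(f_expected, rel=1e-10)


def test_mic_fallback_is_flagged(planted):
    matrix, y = planted
    assert "nmi" in rank_features(matrix, y, "mic").method


def test_rankings_scores_non_increasing(planted):
    matrix, y = planted
    for method in RANKING_METHODS:
        scores = rank_features(matrix, y, method, seed=0).scores
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


# --- PageRank aggregation --------------------------------------------------


def test_identical_rankings_preserved():
    names = ["a", "b", "c", "d"]
    rankings = [
        FeatureRanking(f"m{i}", names, [4.0, 3.0, 2.0, 1.0]) for i in range(7)
    ]
    agg = aggregate_pagerank(rankings)
    assert agg.ordered == names
    assert sum(agg.scores) == pytest.approx(1.0, abs=1e-9)


def test_unanimous_top_feature_wins(rng):
    names = [f"x{j}" for j in range(6)]
    rankings = []
    for i in range(5):
        rest = list(rng.permutation(names[1:]))
        order = [names[0]] + rest
        rankings.append(FeatureRanking(f"m{i}", order, list(range(6, 0, -1))))
    assert aggregate_pagerank(rankings).ordered[0] == "x0"


def test_pagerank_matches_brute_force_power_iteration():
    """4 features, 3 hand-built rankings vs direct stationary distribution."""
    names = ["a", "b", "c", "d"]
    orders = [
        ["a", "b", "c", "d"],
        ["b", "a", "d", "c"],
        ["a", "c", "b", "d"],
    ]
    rankings = [
        FeatureRanking(f"m{i}", o, [3.0, 2.0, 1.0, 0.0]) for i, o in enumerate(orders)
    ]
    agg = aggregate_pagerank(rankings, damping=0.85)

    # independent brute force on the 4x4 transition matrix
    idx = {n: i for i, n in enumerate(names)}
    W = np.zeros((4, 4))
    for o in orders:
        for a in range(4):
            for b in range(a + 1, 4):
                W[idx[o[b]], idx[o[a]]] += 1  # dominated -> dominating
    P = W / W.sum(axis=1, keepdims=True)
    r = np.full(4, 0.25)
    for _ in range(5000):
        r = 0.15 / 4 + 0.85 * P.T @ r
    r /= r.sum()
    expected = [names[i] for i in np.argsort(-r)]
    assert agg.ordered == expected
    got = dict(zip(agg.ordered, agg.scores))
    for n, i in idx.items():
        assert got[n] == pytest.approx(r[i], abs=1e-6)


def test_pagerank_agrees_with_networkx():
    networkx = pytest.importorskip("networkx")
    names = ["a", "b", "c", "d", "e"]
    rng = np.random.default_rng(3)
    orders = [list(rng.permutation(names)) for _ in range(4)]
    rankings = [
        FeatureRanking(f"m{i}", o, [5.0, 4.0, 3.0, 2.0, 1.0])
        for i, o in enumerate(orders)
    ]
    agg = aggregate_pagerank(rankings)
    G = networkx.DiGraph()
    G.add_nodes_from(names)
    for o in orders:
        for a in range(5):
            for b in range(a + 1, 5):
                u, v = o[b], o[a]
                w = G.get_edge_data(u, v, {}).get("weight", 0)
                G.add_edge(u, v, weight=w + 1)
    nx_scores = networkx.pagerank(G, alpha=0.85, tol=1e-12, max_iter=1000)
    got = dict(zip(agg.ordered, agg.scores))
    for n in names:
        assert got[n] == pytest.approx(nx_scores[n], abs=1e-6)


def test_mismatched_feature_sets_error():
    a = FeatureRanking("a", ["x", "y"], [1.0, 0.0])
    b = FeatureRanking("b", ["x", "z"], [1.0, 0.0])
    with pytest.raises(ValueError, match="different feature set"):
        aggregate_pagerank([a, b])


# --- forward selection -----------------------------------------------------


def test_forward_select_finds_planted_feature(rng):
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 21))
    X[:, 0] = y + rng.normal(scale=0.1, size=n)
    matrix = make_matrix(X)
    ranking = rank_features(matrix, y, "anova")
    res = forward_select(ranking, matrix, y, folds=5, seed=0)
    assert "f000" in res.selected
    assert res.best_accuracy >= 0.9
    assert len(res.trace) == 21
    # reported best is the maximum over prefixes
    assert res.best_accuracy == pytest.approx(max(acc for _, acc in res.trace))


def test_forward_select_single_feature_dataset(rng):
    y = np.repeat([0, 1], 15)
    X = rng.normal(size=(30, 1))
    matrix = make_matrix(X)
    res = forward_select(rank_features(matrix, y, "anova"), matrix, y, folds=3, seed=0)
    assert res.selected == ["f000"]


def test_forward_select_shortest_prefix_tie_break():
    """A second exactly duplicated informative column cannot beat the
    single-column prefix, so the shorter prefix must win."""
    y = np.repeat([0, 1], 20)
    x = y.astype(float)
    X = np.column_stack([x, x])
    matrix = make_matrix(X)
    ranking = FeatureRanking("manual", ["f000", "f001"], [1.0, 0.5])
    res = forward_select(ranking, matrix, y, folds=4, seed=0)
    assert res.selected == ["f000"]


# --- reduction rounds ------------------------------------------------------


def test_reduce_once_deterministic_and_never_grows(planted):
    matrix, y = planted
    a = reduce_once(matrix, y, seed=1, folds=4)
    b = reduce_once(matrix, y, seed=1, folds=4)
    assert a.selected == b.selected
    assert len(a.selected) <= matrix.shape[1]
    # applying again to the reduced matrix cannot grow it
    again = reduce_once(a.matrix, y, seed=1, folds=4)
    assert len(again.selected) <= len(a.selected)


def test_iterative_reduce_reaches_fixed_point(planted):
    matrix, y = planted
    res = iterative_reduce(matrix, y, max_rounds=5, seed=1, folds=4)
    assert 1 <= res.rounds <= 5
    assert res.matrix is not None
    assert set(res.selected) <= set(matrix.feature_names)
    # accuracy of the reduced model stays close to the full model
    full = cv_accuracy(default_evaluator(1), matrix.values, y, folds=4, seed=1)
    assert res.best_accuracy >= full - 0.05


def test_iterative_reduce_requires_rounds(planted):
    matrix, y = planted
    with pytest.raises(ValueError):
        iterative_reduce(matrix, y, max_rounds=0)


# --- GA selector -----------------------------------------------------------


def test_ga_beats_single_features_on_xor(rng):
    """Two features informative only jointly (XOR): the evolved subset must
    do at least as well as any single-feature subset."""
    n = 200
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = a ^ b
    X = rng.normal(size=(n, 32)) * 0.5
    X[:, 0] += a
    X[:, 1] += b
    matrix = make_matrix(X)
    res = ga_select(matrix, y, population=16, generations=8, folds=4, seed=2)
    single_best = max(
        cv_accuracy(default_evaluator(2), X[:, [j]], y, folds=4, seed=2)
        for j in (0, 1)
    )
    subset_acc = cv_accuracy(
        default_evaluator(2), matrix.subset(res.selected).values, y, folds=4, seed=2
    )
    assert subset_acc >= single_best - 1e-9


def test_ga_reproducible_and_small_population(planted):
    matrix, y = planted
    r1 = ga_select(matrix, y, population=2, generations=1, folds=3, seed=9)
    r2 = ga_select(matrix, y, population=2, generations=1, folds=3, seed=9)
    assert r1.selected == r2.selected
    assert len(r1.selected) >= 1
    with pytest.raises(ValueError):
        ga_select(matrix, y, population=1)
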