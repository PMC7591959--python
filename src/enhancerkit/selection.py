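"""Ensemble feature ranking, PageRank aggregation and forward selection.

The dimension-reduction engine: seven feature rankers (ANOVA F, chi-square,
normalized mutual information standing in for MIC, L1-logistic weights,
greedy mRMR, RFE, and MRMD relevance+distance) are aggregated by a
PageRank vote over pairwise dominances, and the aggregate order is turned
into a subset by forward addition with cross-validated accuracy. One such
round is ``reduce_once``; ``iterative_reduce`` repeats rounds until the
subset stops shrinking (the fixed point). ``ga_select`` is an alternative
evolutionary selector over bit-mask chromosomes.

PageRank aggregation works on a directed graph with one node per feature;
for every ranking and every pair (i ranked above j) there is an edge
j -> i, so stationary mass flows toward features that many rankers place
high. Damping defaults to 0.85 and iteration runs to 1e-9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, chi2 as _sk_chi2, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .encoders import FeatureMatrix

logger = logging.getLogger(__name__)

RANKING_METHODS = ("anova", "chi2", "mic", "lasso", "mrmr", "rfe", "mrmd")

_N_BINS = 8  # quantile bins for mutual-information estimates


@dataclass
class FeatureRanking:
    """Feature names ordered best-first with non-increasing scores."""

    method: str
    ordered: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.ordered) != len(self.scores):
            raise ValueError("ordered and scores must be parallel")
        if any(b > a + 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError(f"{self.method}: scores must be non-increasing")

    def top(self, m: int) -> "FeatureRanking":
        return FeatureRanking(self.method, self.ordered[:m], self.scores[:m])


@dataclass
class SelectionResult:
    """Outcome of one selection procedure."""

    selected: list[str]
    trace: list[tuple[int, float]]
    rounds: int = 1
    best_accuracy: float = float("nan")
    note: str = ""
    matrix: FeatureMatrix | None = None


def default_evaluator(seed: int = 0) -> BaseEstimator:
    """Random forest used to score candidate subsets (the validation
    classifier of the dimension-reduction loop)."""
    return RandomForestClassifier(n_estimators=50, random_state=seed, n_jobs=1)


def cv_accuracy(
    estimator: BaseEstimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Pooled stratified k-fold accuracy."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train], y[train])
        correct += int((est.predict(X[test]) == y[test]).sum())
    return correct / len(y)


# ---------------------------------------------------------------------------
# individual rankers


def _validate(matrix: FeatureMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.shape[0] != matrix.values.shape[0]:
        raise ValueError("label vector length does not match matrix rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; ranking undefined")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return y


def _order_by_score(
    method: str, names: Sequence[str], scores: np.ndarray
) -> FeatureRanking:
    """Descending score, ties broken lexicographically by name."""
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0)
    idx = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return FeatureRanking(
        method, [names[i] for i in idx], [float(scores[i]) for i in idx]
    )


def _quantile_bins(X: np.ndarray, bins: int = _N_BINS) -> np.ndarray:
    """Rank-based equal-frequency binning per column -> integer codes."""
    n = X.shape[0]
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, X.shape), axis=0)
    codes = (ranks * bins) // n
    # collapse ties: identical values must land in one bin
    for j in range(X.shape[1]):
        _, inv = np.unique(X[:, j], return_inverse=True)
        first = np.full(inv.max() + 1, bins, dtype=int)
        np.minimum.at(first, inv, codes[:, j])
        codes[:, j] = first[inv]
    return codes.astype(np.int64)


def _entropy(counts: np.ndarray, axis=None) -> np.ndarray:
    total = counts.sum(axis=axis, keepdims=True)
    p = np.divide(counts, total, out=np.zeros_like(counts, dtype=float), where=total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=axis)


def _mi_columns_vs_label(codes: np.ndarray, y: np.ndarray, bins: int = _N_BINS) -> np.ndarray:
    """Mutual information (nats) between each binned column and binary y."""
    n, p = codes.shape
    joint = codes * 2 + y[:, None]  # (n, p) in [0, 2*bins)
    flat = joint + np.arange(p)[None, :] * (2 * bins)
    counts = np.bincount(flat.ravel(), minlength=p * 2 * bins).reshape(p, bins, 2)
    hx = _entropy(counts.sum(axis=2), axis=1)
    hy = _entropy(counts.sum(axis=1), axis=1)
    hxy = _entropy(counts.reshape(p, -1), axis=1)
    return hx + hy - hxy


def _nmi_columns_vs_label(codes: np.ndarray, y: np.ndarray, bins: int = _N_BINS) -> np.ndarray:
    n, p = codes.shape
    joint = codes * 2 + y[:, None]
    flat = joint + np.arange(p)[None, :] * (2 * bins)
    counts = np.bincount(flat.ravel(), minlength=p * 2 * bins).reshape(p, bins, 2)
    hx = _entropy(counts.sum(axis=2), axis=1)
    hy = _entropy(counts.sum(axis=1), axis=1)
    mi = hx + hy - _entropy(counts.reshape(p, -1), axis=1)
    denom = np.sqrt(hx * hy)
    return np.divide(mi, denom, out=np.zeros_like(mi), where=denom > 0)


def _mi_one_vs_columns(
    code_s: np.ndarray, codes: np.ndarray, bins: int = _N_BINS
) -> np.ndarray:
    """MI between one binned column and each column of ``codes``."""
    n, p = codes.shape
    joint = codes * bins + code_s[:, None]
    flat = joint + np.arange(p)[None, :] * (bins * bins)
    counts = np.bincount(flat.ravel(), minlength=p * bins * bins).reshape(p, bins, bins)
    hx = _entropy(counts.sum(axis=2), axis=1)
    hs = _entropy(counts.sum(axis=1), axis=1)
    return hx + hs - _entropy(counts.reshape(p, -1), axis=1)


def _rank_anova(matrix, y, seed):
    f, _ = f_classif(matrix.values, y)
    return _order_by_score("anova", matrix.feature_names, f)


def _rank_chi2(matrix, y, seed):
    X = MinMaxScaler().fit_transform(matrix.values)
    scores, _ = _sk_chi2(X, y)
    return _order_by_score("chi2", matrix.feature_names, scores)


def _rank_mic(matrix, y, seed):
    codes = _quantile_bins(matrix.values)
    nmi = _nmi_columns_vs_label(codes, y)
    return _order_by_score("mic(nmi)", matrix.feature_names, nmi)


def _rank_lasso(matrix, y, seed):
    X = MinMaxScaler().fit_transform(matrix.values)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed, max_iter=2000
    )
    model.fit(X, y)
    return _order_by_score("lasso", matrix.feature_names, np.abs(model.coef_[0]))


def _rank_mrmr(matrix, y, seed):
    """Greedy max-relevance-min-redundancy, mutual-information variant.

    Picks the most label-relevant feature first, then repeatedly the
    feature maximizing MI(f; y) - mean MI(f; already selected). Scores are
    the descending pick positions (the greedy criterion itself is not
    monotone).
    """
    names = matrix.feature_names
    p = len(names)
    codes = _quantile_bins(matrix.values)
    relevance = _mi_columns_vs_label(codes, y)
    remaining = list(range(p))
    red_sum = np.zeros(p)
    order: list[int] = []
    first = min(remaining, key=lambda i: (-relevance[i], names[i]))
    order.append(first)
    remaining.remove(first)
    while remaining:
        rem = np.array(remaining)
        red_sum[rem] += _mi_one_vs_columns(codes[:, order[-1]], codes[:, rem])
        crit = relevance[rem] - red_sum[rem] / len(order)
        best_pos = min(
            range(len(rem)), key=lambda i: (-crit[i], names[rem[i]])
        )
        order.append(int(rem[best_pos]))
        remaining.remove(int(rem[best_pos]))
    return FeatureRanking(
        "mrmr", [names[i] for i in order], [float(p - r) for r in range(p)]
    )


def _rank_rfe(matrix, y, seed):
    """Recursive feature elimination with an L2-logistic base learner."""
    X = MinMaxScaler().fit_transform(matrix.values)
    p = X.shape[1]
    if p == 1:
        return FeatureRanking("rfe", list(matrix.feature_names), [1.0])
    step = max(1, p // 20)  # drop 5% per iteration at scale
    est = LogisticRegression(max_iter=2000, random_state=seed)
    rfe = RFE(est, n_features_to_select=1, step=step)
    rfe.fit(X, y)
    # ranking_ is 1 for best; convert to descending scores
    scores = (p - rfe.ranking_).astype(float)
    return _order_by_score("rfe", matrix.feature_names, scores)


def _rank_mrmd(matrix, y, seed, metric: str = "euclidean"):
    """Max-Relevance-Max-Distance: |Pearson r with label| plus mean
    distance to the other features, each min-max normalized."""
    X = MinMaxScaler().fit_transform(matrix.values)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore"):
        rel = np.abs(np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1), 0.0))
    D = pairwise_distances(X.T, metric=metric)
    dist = D.sum(axis=1) / max(1, X.shape[1] - 1)

    def norm01(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    return _order_by_score("mrmd", matrix.feature_names, norm01(rel) + norm01(dist))


_RANKERS: dict[str, Callable] = {
    "anova": _rank_anova,
    "chi2": _rank_chi2,
    "mic": _rank_mic,
    "lasso": _rank_lasso,
    "mrmr": _rank_mrmr,
    "rfe": _rank_rfe,
    "mrmd": _rank_mrmd,
}


def rank_features(
    matrix: FeatureMatrix, y: Sequence[int], method: str, seed: int = 0
) -> FeatureRanking:
    """Rank all features by one of the seven methods; deterministic given
    the seed. Constant features score 0, they are never an error."""
    if method not in _RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {RANKING_METHODS}")
    yv = _validate(matrix, np.asarray(y))
    constant = np.ptp(matrix.values, axis=0) == 0
    if not constant.any():
        return _RANKERS[method](matrix, yv, seed)
    # constant features carry no information: score 0, ranked last under
    # every method (some greedy criteria would otherwise place them early)
    live_names = [n for n, c in zip(matrix.feature_names, constant) if not c]
    const_names = sorted(n for n, c in zip(matrix.feature_names, constant) if c)
    if not live_names:
        return FeatureRanking(method, const_names, [0.0] * len(const_names))
    live = matrix.subset(live_names)
    ranking = _RANKERS[method](live, yv, seed)
    floor = min(0.0, min(ranking.scores))
    return FeatureRanking(
        ranking.method,
        ranking.ordered + const_names,
        ranking.scores + [floor] * len(const_names),
    )


# ---------------------------------------------------------------------------
# PageRank aggregation


def aggregate_pagerank(
    rankings: Sequence[FeatureRanking],
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> FeatureRanking:
    """Aggregate rankings by PageRank over the pairwise-dominance graph.

    Node j links to node i whenever a ranking places i above j, so
    endorsement flows from dominated to dominating features; the stationary
    distribution orders the aggregate (ties broken lexicographically).
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    nodes = sorted(rankings[0].ordered)
    for r in rankings[1:]:
        if sorted(r.ordered) != nodes:
            raise ValueError(f"ranking {r.method!r} covers a different feature set")
    p = len(nodes)
    if p == 1:
        return FeatureRanking("pagerank", list(nodes), [1.0])
    index = {n: i for i, n in enumerate(nodes)}
    # W[j, i] = number of rankings placing i strictly above j
    W = np.zeros((p, p))
    for r in rankings:
        pos = np.empty(p)
        for rank_pos, name in enumerate(r.ordered):
            pos[index[name]] = rank_pos
        W += pos[None, :] < pos[:, None]
    out = W.sum(axis=1)
    dangling = out == 0
    P = np.divide(W, out[:, None], out=np.zeros_like(W), where=out[:, None] > 0)
    score = np.full(p, 1.0 / p)
    teleport = (1.0 - damping) / p
    for _ in range(max_iter):
        new = teleport + damping * (P.T @ score + dangling @ score / p)
        if np.abs(new - score).sum() < tol:
            score = new
            break
        score = new
    score = score / score.sum()
    idx = sorted(range(p), key=lambda i: (-score[i], nodes[i]))
    return FeatureRanking(
        "pagerank", [nodes[i] for i in idx], [float(score[i]) for i in idx]
    )


# ---------------------------------------------------------------------------
# forward addition and reduction rounds


def forward_select(
    ranking: FeatureRanking,
    matrix: FeatureMatrix,
    y: Sequence[int],
    evaluator: BaseEstimator | None = None,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Positive-addition selection along a ranking.

    Features are added best-first; after each addition the stratified CV
    accuracy is recorded. The selected subset is the shortest prefix
    attaining the maximum accuracy.
    """
    y = np.asarray(y, dtype=int)
    evaluator = evaluator if evaluator is not None else default_evaluator(seed)
    sub = matrix.subset(ranking.ordered)
    trace: list[tuple[int, float]] = []
    best_acc, best_size = -1.0, 0
    for size in range(1, len(ranking.ordered) + 1):
        acc = cv_accuracy(evaluator, sub.values[:, :size], y, folds=folds, seed=seed)
        trace.append((size, acc))
        if acc > best_acc + 1e-12:
            best_acc, best_size = acc, size
    return SelectionResult(
        selected=ranking.ordered[:best_size],
        trace=trace,
        rounds=1,
        best_accuracy=best_acc,
    )


def reduce_once(
    matrix: FeatureMatrix,
    y: Sequence[int],
    evaluator: BaseEstimator | None = None,
    seed: int = 0,
    folds: int = 10,
    methods: Sequence[str] = RANKING_METHODS,
    max_scan: int | None = 120,
) -> SelectionResult:
    """One full reduction round: rank by every method, aggregate with
    PageRank, forward-select along the aggregate order.

    ``max_scan`` caps how deep the forward scan walks into the aggregate
    ranking (ranking itself always covers all features); None scans all.
    """
    y = np.asarray(y, dtype=int)
    rankings = [rank_features(matrix, y, m, seed=seed) for m in methods]
    agg = aggregate_pagerank(rankings)
    if max_scan is not None and len(agg.ordered) > max_scan:
        agg = agg.top(max_scan)
    result = forward_select(agg, matrix, y, evaluator=evaluator, folds=folds, seed=seed)
    result.matrix = matrix.subset(result.selected)
    return result


def iterative_reduce(
    matrix: FeatureMatrix,
    y: Sequence[int],
    evaluator: BaseEstimator | None = None,
    max_rounds: int = 8,
    seed: int = 0,
    folds: int = 10,
    methods: Sequence[str] = RANKING_METHODS,
    max_scan: int | None = 120,
) -> SelectionResult:
    """Repeat ``reduce_once`` until the subset stops shrinking.

    The fixed point ("the dimension can no longer be reduced") is reached
    when a round returns a subset no smaller than its input; subset size is
    non-increasing across rounds by construction.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    y = np.asarray(y, dtype=int)
    current = matrix
    trace: list[tuple[int, float]] = []
    best_acc = float("nan")
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        res = reduce_once(
            current, y, evaluator=evaluator, seed=seed, folds=folds,
            methods=methods, max_scan=max_scan,
        )
        trace.extend(res.trace)
        best_acc = res.best_accuracy
        assert res.matrix is not None
        if res.matrix.shape[1] >= current.shape[1]:
            current = res.matrix
            break
        current = res.matrix
    return SelectionResult(
        selected=list(current.feature_names),
        trace=trace,
        rounds=rounds,
        best_accuracy=best_acc,
        matrix=current,
    )


# ---------------------------------------------------------------------------
# evolutionary selector


def ga_select(
    matrix: FeatureMatrix,
    y: Sequence[int],
    evaluator: BaseEstimator | None = None,
    population: int = 20,
    generations: int = 10,
    mutation_rate: float = 0.02,
    parsimony: float = 0.01,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Genetic-algorithm feature selection over bit-mask chromosomes.

    Fitness is CV accuracy minus ``parsimony`` times the selected fraction;
    tournament selection (size 2), uniform crossover, per-bit mutation and
    elitism of one. Fully reproducible from the seed.
    """
    if population < 2:
        raise ValueError("population must be >= 2")
    y = np.asarray(y, dtype=int)
    evaluator = evaluator if evaluator is not None else default_evaluator(seed)
    rng = np.random.default_rng(seed)
    p = matrix.shape[1]
    X = matrix.values
    pop = rng.random((population, p)) < 0.5
    # guarantee non-empty chromosomes
    for row in pop:
        if not row.any():
            row[rng.integers(p)] = True

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = -1.0
            else:
                acc = cv_accuracy(evaluator, X[:, mask], y, folds=folds, seed=seed)
                cache[key] = acc - parsimony * mask.mean()
        return cache[key]

    trace: list[tuple[int, float]] = []
    fits = np.array([fitness(m) for m in pop])
    for _ in range(generations):
        elite = pop[int(np.argmax(fits))].copy()
        children = [elite]
        while len(children) < population:
            def pick() -> np.ndarray:
                a, b = rng.integers(population, size=2)
                return pop[a] if fits[a] >= fits[b] else pop[b]

            pa, pb = pick(), pick()
            cross = rng.random(p) < 0.5
            child = np.where(cross, pa, pb)
            child = child ^ (rng.random(p) < mutation_rate)
            children.append(child)
        pop = np.array(children)
        fits = np.array([fitness(m) for m in pop])
        best = pop[int(np.argmax(fits))]
        trace.append((int(best.sum()), float(np.max(fits))))

    best = pop[int(np.argmax(fits))]
    note = ""
    if not best.any():
        # degenerate: fall back to the best single feature
        singles = [fitness(np.eye(p, dtype=bool)[j]) for j in range(p)]
        best = np.eye(p, dtype=bool)[int(np.argmax(singles))]
        note = "empty mask; fell back to best single feature"
        logger.warning(note)
    selected = [n for n, m in zip(matrix.feature_names, best) if m]
    return SelectionResult(
        selected=selected,
        trace=trace or [(int(best.sum()), float(np.max(fits)))],
        rounds=generations,
        best_accuracy=float(np.max(fits)),
        note=note,
        matrix=matrix.subset(selected),
    )
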