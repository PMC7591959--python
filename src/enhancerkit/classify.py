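"""Classifiers, cross-validation, evaluation metrics and confidence voting.

Binary evaluation uses the four standard confusion-derived quantities:
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), total accuracy
Acc = (TP+TN)/N and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC defined
as 0 whenever a denominator factor vanishes.

Cross-validated metrics are reported both pooled (confusion counts summed
across folds, the headline number) and per fold. The ensemble combiner
keeps, per record, the single classifier prediction with the highest
class probability, with a fixed priority order breaking exact ties.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for binary classification."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("length mismatch between truth and predictions")
        return cls(
            TP=int(((yt == 1) & (yp == 1)).sum()),
            FP=int(((yt == 0) & (yp == 1)).sum()),
            TN=int(((yt == 0) & (yp == 0)).sum()),
            FN=int(((yt == 1) & (yp == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Acc in [0,1] and Mcc in [-1,1]."""

    Sn: float
    Sp: float
    Acc: float
    Mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "Mcc": self.Mcc}


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Derive Sn/Sp/Acc/MCC from confusion counts.

    A class entirely absent from the evaluation makes Sn or Sp an empty
    ratio; it is reported as 0. Any zero factor in the MCC denominator
    yields Mcc = 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero samples")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricSet(Sn=sn, Sp=sp, Acc=acc, Mcc=mcc)


@dataclass
class CVResult:
    """Cross-validation outcome: pooled metrics plus per-fold detail."""

    pooled: MetricSet
    per_fold: list[MetricSet]
    counts: ConfusionCounts

    @property
    def mean_fold(self) -> MetricSet:
        return MetricSet(
            Sn=float(np.mean([m.Sn for m in self.per_fold])),
            Sp=float(np.mean([m.Sp for m in self.per_fold])),
            Acc=float(np.mean([m.Acc for m in self.per_fold])),
            Mcc=float(np.mean([m.Mcc for m in self.per_fold])),
        )


def crossvalidate(
    X: np.ndarray,
    y: Sequence[int],
    estimator: BaseEstimator,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled confusion counts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; "
            f"use at most that many folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_fold: list[MetricSet] = []
    for train, test in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train], y[train])
        fold_counts = ConfusionCounts.from_predictions(y[test], est.predict(X[test]))
        per_fold.append(compute_metrics(fold_counts))
        pooled = pooled + fold_counts
    return CVResult(pooled=compute_metrics(pooled), per_fold=per_fold, counts=pooled)


# ---------------------------------------------------------------------------
# classifiers


def train_random_forest(
    X: np.ndarray, y: Sequence[int], n_trees: int = 100, seed: int = 0
) -> RandomForestClassifier:
    """Majority-vote forest of decision trees; class probability is the
    tree-vote fraction."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(np.asarray(X, float), y)
    return clf


def make_third_classifier(seed: int = 0) -> BaseEstimator:
    """Pluggable third probabilistic classifier for the voting ensemble
    (gradient-boosted trees by default)."""
    return GradientBoostingClassifier(random_state=seed)


@dataclass(frozen=True)
class GridSpec:
    """log2-spaced (c, g) grid for the RBF-SVM search.

    Defaults span c = 2^-5..2^15 and g = 2^-15..2^3 in steps of 2^2, the
    classic libSVM grid; it contains the optimum reported for the
    enhancer benchmark (c = 2^13 = 8192, g = 2^-9 = 0.001953125).
    """

    c_values: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
    g_values: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))

    def __post_init__(self) -> None:
        if not self.c_values or not self.g_values:
            raise ValueError("grid must be non-empty")
        if min(self.c_values) <= 0 or min(self.g_values) <= 0:
            raise ValueError("grid values must be positive")


def train_svm_grid(
    X: np.ndarray,
    y: Sequence[int],
    grid: GridSpec | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[SVC, tuple[float, float]]:
    """RBF-SVM with (c, g) chosen by inner CV accuracy.

    Ties favour the smaller c, then the smaller g. The returned model is
    refit on all data with probability estimates enabled (for voting).
    """
    grid = grid or GridSpec()
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-1.0, float("inf"), float("inf"))
    best_cg = None
    for c in sorted(grid.c_values):
        for g in sorted(grid.g_values):
            correct = 0
            for train, test in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X[train], y[train])
                correct += int((clf.predict(X[test]) == y[test]).sum())
            acc = correct / len(y)
            key = (acc, -c, -g)
            if key > (best[0], -best[1], -best[2]):
                best = (acc, c, g)
                best_cg = (c, g)
    assert best_cg is not None
    # calibrated probabilities so the voting stage gets honest confidences
    model = CalibratedClassifierCV(
        SVC(C=best_cg[0], gamma=best_cg[1], kernel="rbf"),
        ensemble=False,
        cv=StratifiedKFold(n_splits=min(folds, 5), shuffle=True, random_state=seed),
    )
    model.fit(X, y)
    return model, best_cg


# ---------------------------------------------------------------------------
# predictions and voting


@dataclass(frozen=True)
class Prediction:
    """One classifier's call on one record."""

    record_id: str
    label: int
    confidence: float
    source: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


def predict_with_confidence(
    clf: BaseEstimator, X: np.ndarray, record_ids: Sequence[str], source: str
) -> list[Prediction]:
    """Per-record argmax label with its class probability as confidence."""
    proba = clf.predict_proba(np.asarray(X, float))
    pos_col = list(clf.classes_).index(1)
    out = []
    for rid, p in zip(record_ids, proba[:, pos_col]):
        label = int(p >= 0.5)
        out.append(Prediction(rid, label, float(max(p, 1 - p)), source))
    return out


#: Fixed tie-break order when two classifiers report equal confidence.
DEFAULT_PRIORITY = ("svm", "rf", "third", "attention-lstm")


def vote_highest_confidence(
    predictions: Iterable[Prediction],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, Prediction]:
    """Keep, per record, the prediction with the highest confidence.

    Exact confidence ties go to the classifier appearing earliest in
    ``priority`` (unknown sources rank after all listed ones).
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("no predictions to vote on")
    rank = {name: i for i, name in enumerate(priority)}

    def sort_key(p: Prediction):
        return (-p.confidence, rank.get(p.source, len(priority)), p.source)

    winners: dict[str, Prediction] = {}
    order: dict[str, list[Prediction]] = {}
    for p in preds:
        order.setdefault(p.record_id, []).append(p)
    for rid, group in order.items():
        winners[rid] = min(group, key=sort_key)
    return winners


def save_model(model: object, path: str | Path) -> None:
    """Persist a fitted model to a single-file pickle archive."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> object:
    with open(path, "rb") as fh:
        return pickle.load(fh)
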