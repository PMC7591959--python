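"""End-to-end identification and classification workflows.

``run_identification`` mirrors the feature-model route: encode with the
seven retained composition schemes, reduce each scheme's matrix once,
merge, reduce the merged matrix iteratively to its fixed point, then
cross-validate the final subset with a random forest, an RBF-SVM (grid
searched) and a third probabilistic classifier.

``run_classification`` runs two routes on two-tier data: the feature route
with highest-confidence voting across the three classifiers, and the
recurrent route (3-mer tokens -> skip-gram embeddings -> attention LSTM)
evaluated on a held-out split.

Every run emits a manifest (config hash, seed, package version) so a rerun
with the same inputs reproduces the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .classify import (
    GridSpec,
    compute_metrics,
    ConfusionCounts,
    crossvalidate,
    make_third_classifier,
    predict_with_confidence,
    train_random_forest,
    train_svm_grid,
    vote_highest_confidence,
)
from .encoders import ENCODERS, FeatureMatrix, default_identification_encoders, merge_matrices
from .io import LabeledDataset
from .selection import default_evaluator, iterative_reduce, reduce_once
from .rnn import RnnConfig, predict as rnn_predict, tokenize, train_attention_lstm, train_embeddings


@dataclass
class PipelineConfig:
    """Knobs shared by both workflows; the master seed reaches every
    stochastic stage."""

    encoders: list[tuple[str, dict]] = field(
        default_factory=default_identification_encoders
    )
    folds: int = 10
    selection_folds: int = 5
    max_rounds: int = 8
    max_scan: int = 120
    seed: int = 0
    svm_grid: GridSpec | None = None
    rnn: RnnConfig | None = None
    out_dir: str | None = None

    def manifest(self) -> dict[str, Any]:
        blob = json.dumps(
            {
                "encoders": self.encoders,
                "folds": self.folds,
                "selection_folds": self.selection_folds,
                "max_rounds": self.max_rounds,
                "max_scan": self.max_scan,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
            "version": __version__,
        }


#: Minimal schema for workflow reports: required keys and their types.
REPORT_SCHEMA: dict[str, dict[str, type]] = {
    "identification": {
        "workflow": str,
        "stages": list,
        "selected_features": list,
        "final_dimension": int,
        "metrics": dict,
        "manifest": dict,
    },
    "classification": {
        "workflow": str,
        "final_dimension": int,
        "voted_metrics": dict,
        "rnn_metrics": dict,
        "manifest": dict,
    },
}


def validate_report(report: dict[str, Any]) -> None:
    """Raise ValueError unless the report matches its workflow schema."""
    workflow = report.get("workflow")
    if workflow not in REPORT_SCHEMA:
        raise ValueError(f"unknown workflow {workflow!r}")
    for key, typ in REPORT_SCHEMA[workflow].items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} should be {typ.__name__}")
    manifest = report["manifest"]
    for key in ("config_hash", "seed", "version"):
        if key not in manifest:
            raise ValueError(f"manifest missing {key!r}")


def encode_all(
    dataset: LabeledDataset, encoders: Sequence[tuple[str, dict]]
) -> list[FeatureMatrix]:
    return [ENCODERS[name](dataset.records, **kwargs) for name, kwargs in encoders]


def _maybe_persist(matrix: FeatureMatrix, out_dir: str | None, name: str) -> None:
    if out_dir:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(path / f"{name}.csv")


def run_identification(
    dataset: LabeledDataset, config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Encode -> per-scheme reduce -> merge -> iterative reduce -> classify."""
    config = config or PipelineConfig()
    y = np.asarray(dataset.y)
    seed = config.seed
    stages: list[dict[str, Any]] = []

    matrices = encode_all(dataset, config.encoders)
    reduced = []
    for m in matrices:
        _maybe_persist(m, config.out_dir, f"encoded_{m.tag}")
        res = reduce_once(
            m, y, evaluator=default_evaluator(seed), seed=seed,
            folds=config.selection_folds, max_scan=config.max_scan,
        )
        assert res.matrix is not None
        reduced.append(res.matrix)
        stages.append(
            {"stage": "reduce", "encoder": m.tag,
             "dim_in": m.shape[1], "dim_out": res.matrix.shape[1]}
        )
        _maybe_persist(res.matrix, config.out_dir, f"reduced_{m.tag}")

    merged = merge_matrices(reduced)
    stages.append({"stage": "merge", "dim_out": merged.shape[1]})
    _maybe_persist(merged, config.out_dir, "merged")

    final = iterative_reduce(
        merged, y, evaluator=default_evaluator(seed), max_rounds=config.max_rounds,
        seed=seed, folds=config.selection_folds, max_scan=config.max_scan,
    )
    assert final.matrix is not None
    stages.append(
        {"stage": "iterative_reduce", "dim_in": merged.shape[1],
         "dim_out": final.matrix.shape[1], "rounds": final.rounds}
    )
    _maybe_persist(final.matrix, config.out_dir, "final")

    X = final.matrix.values
    grid = config.svm_grid or GridSpec(
        c_values=(1.0, 8.0, 64.0), g_values=(0.5, 0.03125, 0.001953125)
    )
    metrics = {}
    rf_cv = crossvalidate(
        X, y, train_random_forest(X, y, seed=seed).__class__(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        folds=config.folds, seed=seed,
    )
    metrics["rf"] = rf_cv.pooled.as_dict()
    from sklearn.svm import SVC

    svm_model, cg = train_svm_grid(X, y, grid=grid, folds=config.folds, seed=seed)
    svm_cv = crossvalidate(
        X, y, SVC(C=cg[0], gamma=cg[1], kernel="rbf"), folds=config.folds, seed=seed
    )
    metrics["svm"] = {**svm_cv.pooled.as_dict(), "c": cg[0], "g": cg[1]}
    third_cv = crossvalidate(X, y, make_third_classifier(seed), folds=config.folds, seed=seed)
    metrics["third"] = third_cv.pooled.as_dict()

    report = {
        "workflow": "identification",
        "stages": stages,
        "selected_features": final.matrix.feature_names,
        "final_dimension": final.matrix.shape[1],
        "metrics": metrics,
        "manifest": config.manifest(),
    }
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        with open(Path(config.out_dir) / "identification_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def run_classification(
    dataset: LabeledDataset, config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Feature route with confidence voting plus the recurrent route."""
    config = config or PipelineConfig()
    seed = config.seed
    y = np.asarray(dataset.y)
    ids = [r.id for r in dataset.records]

    # feature route: encode + merge + reduce, then vote three classifiers
    matrices = encode_all(dataset, config.encoders)
    merged = merge_matrices(matrices)
    final = iterative_reduce(
        merged, y, evaluator=default_evaluator(seed), max_rounds=config.max_rounds,
        seed=seed, folds=config.selection_folds, max_scan=config.max_scan,
    )
    assert final.matrix is not None
    X = final.matrix.values

    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=0.3, stratify=y, random_state=seed
    )
    grid = config.svm_grid or GridSpec(
        c_values=(1.0, 8.0, 64.0), g_values=(0.5, 0.03125, 0.001953125)
    )
    rf = train_random_forest(X[idx_train], y[idx_train], seed=seed)
    svm, cg = train_svm_grid(
        X[idx_train], y[idx_train], grid=grid, folds=config.selection_folds, seed=seed
    )
    third = make_third_classifier(seed).fit(X[idx_train], y[idx_train])
    test_ids = [ids[i] for i in idx_test]
    preds = (
        predict_with_confidence(rf, X[idx_test], test_ids, "rf")
        + predict_with_confidence(svm, X[idx_test], test_ids, "svm")
        + predict_with_confidence(third, X[idx_test], test_ids, "third")
    )
    voted = vote_highest_confidence(preds)
    y_test = {rid: int(v) for rid, v in zip(test_ids, y[idx_test])}
    counts = ConfusionCounts.from_predictions(
        [y_test[rid] for rid in test_ids], [voted[rid].label for rid in test_ids]
    )
    voted_metrics = compute_metrics(counts).as_dict()

    # recurrent route: 3-mer tokens -> embeddings -> attention LSTM
    rnn_cfg = config.rnn or RnnConfig(seed=seed, epochs=10)
    tokens = tokenize(dataset.records, k=rnn_cfg.k)
    by_id = {t.record_id: t for t in tokens}
    train_tokens = [by_id[ids[i]] for i in idx_train]
    test_tokens = [by_id[ids[i]] for i in idx_test]
    emb = train_embeddings(
        train_tokens, embedding_dim=rnn_cfg.embedding_dim, seed=seed, k=rnn_cfg.k
    )
    model = train_attention_lstm(
        train_tokens, {rid: int(v) for rid, v in zip(ids, y)}, embeddings=emb,
        config=rnn_cfg,
    )
    rnn_preds = rnn_predict(model, test_tokens)
    rnn_counts = ConfusionCounts.from_predictions(
        [y_test[p.record_id] for p in rnn_preds], [p.label for p in rnn_preds]
    )
    rnn_metrics = compute_metrics(rnn_counts).as_dict()

    report = {
        "workflow": "classification",
        "final_dimension": final.matrix.shape[1],
        "voted_metrics": voted_metrics,
        "rnn_metrics": rnn_metrics,
        "svm_c_g": list(cg),
        "manifest": config.manifest(),
    }
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        with open(Path(config.out_dir) / "classification_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
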