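"""Train three probabilistic classifiers and combine them by confidence.

Each classifier reports its class probability per sequence; the voting
combiner keeps, per sequence, the single most confident call, and the
result is scored with Sn/Sp/Acc/MCC.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from enhancerkit import (
    ConfusionCounts,
    GridSpec,
    SimulationConfig,
    compute_metrics,
    encode_kmer,
    generate_dataset,
    make_third_classifier,
    predict_with_confidence,
    train_random_forest,
    train_svm_grid,
    vote_highest_confidence,
)

dataset = generate_dataset(
    SimulationConfig(n_pos=80, n_neg=80, length=100, motifs=["ACGTACGT"],
                     motif_prob=1.0, seed=11)
)
X = encode_kmer(dataset.records, 4).values
y = np.array(dataset.y)
ids = [r.id for r in dataset.records]

train, test = train_test_split(np.arange(len(y)), test_size=0.3, stratify=y, random_state=11)
rf = train_random_forest(X[train], y[train], seed=11)
svm, (c, g) = train_svm_grid(
    X[train], y[train], grid=GridSpec((1.0, 64.0), (0.5, 0.0078125)), folds=5, seed=11
)
third = make_third_classifier(11).fit(X[train], y[train])
print(f"SVM grid chose c={c}, g={g}")

test_ids = [ids[i] for i in test]
preds = (
    predict_with_confidence(rf, X[test], test_ids, "rf")
    + predict_with_confidence(svm, X[test], test_ids, "svm")
    + predict_with_confidence(third, X[test], test_ids, "third")
)
voted = vote_highest_confidence(preds)
winners = [voted[rid].source for rid in test_ids]
print("votes won:", {s: winners.count(s) for s in set(winners)})

metrics = compute_metrics(ConfusionCounts.from_predictions(
    [dataset.labels[rid] for rid in test_ids], [voted[rid].label for rid in test_ids]
))
print("voted metrics:", {k: round(v, 3) for k, v in metrics.as_dict().items()})
print("\nSn/Sp split the accuracy by class; MCC summarizes the whole")
print("confusion table in [-1, 1].")
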