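"""Reduce a merged multi-encoder feature matrix to its informative core.

Generates a balanced synthetic benchmark with two planted 8-mer motifs,
merges three encoder matrices, then runs the ensemble-ranking + PageRank +
forward-addition reduction to a fixed point.
"""

import numpy as np

from enhancerkit import (
    SimulationConfig,
    encode_cksnap,
    encode_kmer,
    encode_pseeiip,
    generate_dataset,
    iterative_reduce,
    merge_matrices,
)

dataset = generate_dataset(
    SimulationConfig(n_pos=60, n_neg=60, length=80,
                     motifs=["ACGTACGT", "GGATCCGG"], motif_prob=1.0, seed=7)
)
merged = merge_matrices([
    encode_kmer(dataset.records, 2),
    encode_kmer(dataset.records, 3),
    encode_pseeiip(dataset.records),
])
print(f"merged feature matrix: {merged.shape[0]} sequences x {merged.shape[1]} features")

result = iterative_reduce(merged, np.array(dataset.y), seed=7, folds=5, max_scan=40)
print(f"reduced to {len(result.selected)} features in {result.rounds} round(s)")
print("selected:", result.selected)
print(f"cross-validated accuracy of the subset: {result.best_accuracy:.3f}")
print("\nThe survivors are k-mer/trinucleotide features overlapping the")
print("planted motifs; accuracy is preserved at a fraction of the width.")
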