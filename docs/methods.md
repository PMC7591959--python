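# Methods

## Scope and data model

The toolkit operates on uniform-alphabet DNA sequences (`{A, C, G, T}`,
uppercased on input) with binary labels. Enhancer benchmarks in this
field are fixed-length fragments (200 bp is the conventional length), so
the position-resolved encoders (ENAC, NCP, ANF, EIIP, one-hot) require
one common length per dataset; the composition encoders (k-mer, RCK-mer,
CKSNAP, PseEIIP) accept any length above their window size. Characters
outside the four-letter alphabet are a hard error by default, with an
explicit `drop_record` opt-in — the encoders' denominators assume a
4-letter alphabet, so silently recoding ambiguity characters would bias
every frequency.

## Encoders

All frequency-type encoders are normalized distributions: k-mer divides
word counts by the window count `L − k + 1`, CKSNAP divides gapped-pair
counts by `L − k − 1` per gap, ENAC normalizes within each window. Column
order is lexicographic with A < C < G < T everywhere; the choice is
arbitrary but fixed, because downstream selection and merging depend on
deterministic column identity. RCK-mer canonicalizes each word to the
lexicographic minimum of the word and its reverse complement and sums the
two members' frequencies (self-complementary words counted once); at
k = 2 this yields the 10 classes AA, AC, AG, AT, CA, CC, CG, GA, GC, TA.
The ENAC window defaults to 5, the common default of composition-feature
tools, and is a parameter. ANF stores unrounded values; its reference
worked example is printed at two decimals, and tests compare at that
precision.

## Synthetic benchmark generator

`simulate.generate_dataset` emulates the structure of a balanced
enhancer benchmark: two classes of i.i.d. per-position background with
`P(G) = P(C) = gc/2`, `P(A) = P(T) = (1 − gc)/2`, and short motifs
overwritten into positives at uniform random positions (non-overlapping
best effort, length never changes). Defaults: 200 bp, balanced classes,
gc = 0.5 for both classes, motif probability 1. Strong/weak "enhancer
strength" is emulated purely as signal-intensity tiers
(`two_tier_dataset`), not as chromatin biology. What passing tests on
this generator show is that the pipeline recovers planted composition and
motif signal at realistic sizes and stays at chance on exact nulls; they
do not show anything about the positional grammar, repeat structure or
GC heterogeneity of real genomic sequence.

## Dimension reduction

One reduction round ranks all features with seven methods, aggregates the
rankings, and forward-selects along the aggregate order:

- ANOVA F and χ² (the latter on min-max-scaled features) are the
  scikit-learn scores.
- The MIC slot is filled by quantile-binned (8 equal-frequency bins)
  normalized mutual information, flagged as `mic(nmi)` in the ranking's
  method name.
- Lasso ranks by absolute L1-logistic coefficients on scaled features.
- mRMR is the greedy mutual-information variant (relevance minus mean
  redundancy against the already-selected set), fully vectorized via
  binned joint counts so it covers every feature.
- RFE eliminates ~5% of features per step with an L2-logistic learner.
- MRMD sums |Pearson r with the label| and mean Euclidean distance to
  the other feature columns, each min-max normalized so the two terms
  are commensurable (the distance metric is a parameter; Euclidean is
  the default).

Constant features are informationless and are placed last with score 0
under every method, which some greedy criteria would not otherwise
guarantee.

Aggregation builds a directed graph with one node per feature and, for
every ranking and every ordered pair (i above j), an edge j → i; PageRank
(damping 0.85, dense power iteration to 1e−9, dangling mass spread
uniformly) scores the nodes and ties break lexicographically. The
pairwise-dominance construction is one concrete reading of "aggregate by
PageRank"; damping and tolerance are parameters. The test suite checks
the implementation against networkx's PageRank and a hand-rolled
stationary-distribution iteration on small graphs.

Forward addition walks the aggregate order, records stratified CV
accuracy after each addition, and keeps the shortest prefix attaining the
maximum — the shortest-prefix tie-break deliberately favours low
dimension. `reduce_once` caps how deep the forward scan walks
(`max_scan`, default 120) so rounds on ~1000-column matrices stay at desk
scale; the ranking itself always covers all features. `iterative_reduce`
repeats rounds until a round fails to shrink the subset, which is the
operational definition of "cannot be reduced further". The subset
evaluator defaults to a 50-tree random forest; anything with the sklearn
estimator interface can be passed.

The GA selector evolves bit-mask chromosomes with tournament selection
(size 2), uniform crossover, per-bit mutation (default 0.02), elitism of
one, and fitness = CV accuracy − 0.01 × selected fraction. The parsimony
weight keeps ties resolving toward smaller subsets without overriding
genuine accuracy differences.

## Classification and evaluation

Cross-validation is stratified; the headline metric set is computed from
confusion counts pooled across folds (micro-average), which is stabler
than averaging per-fold ratios at benchmark sizes of a few thousand;
per-fold metrics are also reported. MCC uses the standard normalized-
determinant form with the zero-denominator convention MCC = 0. The SVM
grid is the classic log2-spaced libSVM grid (c: 2⁻⁵..2¹⁵, g: 2⁻¹⁵..2³,
step 2²), ties resolved toward smaller c then smaller g; the final model
is wrapped in Platt-style calibration so the voting stage receives honest
probabilities. The voting combiner keeps the single most confident
prediction per record, with a fixed classifier priority order for exact
ties. The third ensemble member is pluggable and defaults to gradient-
boosted trees.

## Recurrent route

Sequences are segmented into overlapping 3-mers (stride 1 — the norm for
k-mer embeddings; stride is a parameter). Skip-gram embeddings are
trained with a full softmax over the 65-token vocabulary (64 3-mers plus
a reserved unknown token) — negative sampling would buy nothing at this
vocabulary size. The classifier is a two-layer LSTM, hidden size 100,
with additive attention (`u_t = tanh(W_a h_t + b_a)`, `e_t = v·u_t`,
softmax over time) pooling into a context vector and a sigmoid head,
trained with Adam at learning rate 0.005. Defaults for the unspecified
hyperparameters: embedding dimension 100, 30 epochs, batch size 32.
Forward pass, backpropagation through time and Adam are implemented
directly on numpy arrays; a numerical gradient check in the test suite
verifies the analytic gradients of every parameter tensor, including the
embedding table. Training is seeded and reproducible on one platform;
bit-identical training across platforms is not promised. Non-finite loss
raises an error naming the epoch rather than continuing silently.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: encoder
dual-route checks use 100 random 30–200-mers; planted-feature recovery
uses 20 simulations of 150 samples × 50 features with a 1.2σ per-feature
class shift; the merged-matrix reduction uses 150 sequences of 100 bp,
whose seven default encoders yield a 1016-column matrix; the LSTM
capacity check trains on 200 sequences of 100 bp for 30 epochs; shuffle
nulls use 400 sequences. These sizes are the package's own desk-scale
choices; every stage accepts larger inputs unchanged.

## Known limitations

- The background model is i.i.d. per position; no dinucleotide
  autocorrelation, repeats or isochore structure.
- The MIC slot is an NMI approximation, not the exact maximal
  information coefficient.
- The selective-ensemble classifier family (clustering-and-pruning
  ensembles) is out of scope; the third voting slot takes any
  probabilistic sklearn classifier instead.
- Binary labels only; no multi-class support.
- Published benchmark accuracies on the classic enhancer datasets are
  not reproduced here because those datasets are not bundled; the
  acceptance suite substitutes worked-example and property-based checks.
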