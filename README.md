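# enhancerkit

Enhancers are short non-coding DNA elements (typically studied as fixed
200 bp fragments) that boost transcription of their target genes. Locating
them computationally — and grading located enhancers as strong or weak —
is a standard binary sequence-classification problem in regulatory
genomics. `enhancerkit` is a toolkit for that problem aimed at
computational biologists who want every stage of the classic
composition-feature pipeline available as composable, testable Python:

1. **Nine sequence encoders** mapping a DNA string to a named numeric
   vector: k-mer, reverse-complement k-mer (RCK-mer), ENAC, CKSNAP, NCP,
   ANF, EIIP, PseEIIP and one-hot.
2. **An ensemble dimension-reduction engine**: seven feature rankers
   (ANOVA F, χ², normalized mutual information, L1-logistic weights,
   mRMR, RFE, MRMD) aggregated by a PageRank vote over pairwise
   dominances, followed by forward addition of ranked features under
   cross-validated accuracy, iterated to a fixed point. A genetic-
   algorithm selector is available as an alternative.
3. **Classifiers and evaluation**: random forest, grid-searched RBF-SVM,
   a pluggable third probabilistic classifier, stratified k-fold CV with
   pooled confusion counts, Sn/Sp/Acc/MCC, and a highest-confidence
   voting combiner.
4. **A recurrent route**: 3-mer tokenization, skip-gram (word2vec)
   embeddings, and a two-layer attention LSTM (hidden size 100, Adam at
   lr 0.005) implemented directly in numpy, with per-time-step attention
   weights exposed.
5. **A synthetic benchmark generator** planting motif and GC-composition
   signal of tunable strength, so the whole pipeline is exercisable with
   no external download.

## The core quantities

For a sequence of length `L` (`N_t` in the k-mer notation), the k-mer
frequency of word `w` is `f_w = N_w / (L − k + 1)`, the count of sliding
windows equal to `w` over the number of windows. RCK-mer folds each word
with its reverse complement (16 dinucleotides → 10 canonical classes).
CKSNAP counts ordered base pairs separated by exactly `k` positions, with
denominator `L − k − 1`. ANF attaches to each position `i` the frequency
of that position's base within the prefix `1..i`; EIIP uses the fixed
pseudopotentials A = 0.1260, C = 0.1340, G = 0.0806, T = 0.1335, and
PseEIIP weights each trinucleotide's summed EIIP by its frequency.

Evaluation follows the standard confusion-matrix quantities

    Sn = TP/(TP+FN),  Sp = TN/(TN+FP),  Acc = (TP+TN)/N,
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 when a denominator factor vanishes.

## Worked example

```python
from enhancerkit import SequenceRecord, encode_anf

record = SequenceRecord("demo", "TCGTTCATGG")
anf = encode_anf([record]).values[0].reshape(10, 4)
```

Running `python examples/01_encode_features.py` prints, among other
things:

```
ANF 4-tuples (NCP triple + accumulated frequency), one per position:
  pos  1 T: (0, 0, 1, 1.00)
  pos  2 C: (0, 1, 0, 0.50)
  pos  3 G: (1, 0, 0, 0.33)
  pos  4 T: (0, 0, 1, 0.50)
  pos  5 T: (0, 0, 1, 0.60)
  pos  6 C: (0, 1, 0, 0.33)
  pos  7 A: (1, 1, 1, 0.14)
  pos  8 T: (0, 0, 1, 0.50)
  pos  9 G: (1, 0, 0, 0.22)
  pos 10 G: (1, 0, 0, 0.30)
```

Each line is one position's chemical-property triple (ring structure,
hydrogen bonding, functional group) followed by the accumulated frequency
of that base in the prefix — e.g. position 7 is the only A seen so far,
hence 1/7 ≈ 0.14.

The other examples show the remaining capabilities end to end; e.g.
`python examples/02_select_features.py` merges three encoder matrices
(144 columns) over a motif-planted synthetic benchmark and reduces them:

```
merged feature matrix: 120 sequences x 144 features
reduced to 8 features in 2 round(s)
selected: ['kmer3.ACG', 'kmer3.CGT', 'pseeiip.ACG', 'pseeiip.CGT', ...]
cross-validated accuracy of the subset: 0.975
```

The surviving trinucleotide features tile the planted motifs, and the
8-column model keeps the accuracy of the 144-column one.

There is also a thin CLI (`enhancerkit --help`) exposing each stage
(`simulate`, `encode`, `select`, `train`, `evaluate`, `vote`,
`classify-rnn`) and the two end-to-end workflows
(`run-identification`, `run-classification`).

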