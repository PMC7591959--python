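"""Naive, independent re-implementations of the encoders.

Everything here works by direct string scanning with Python dictionaries —
no numpy vectorization, no code shared with the package — so agreement
with the package encoders is a genuine dual-route check.
"""

from itertools import product

EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}
NCP = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "T": (0, 0, 1)}
ONEHOT = {"A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1)}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def all_kmers(k):
    return ["".join(p) for p in product("ACGT", repeat=k)]


def revcomp(s):
    return "".join(COMP[c] for c in reversed(s))


def naive_kmer(seq, k):
    counts = {w: 0 for w in all_kmers(k)}
    n_windows = len(seq) - k + 1
    for i in range(n_windows):
        counts[seq[i : i + k]] += 1
    return [counts[w] / n_windows for w in all_kmers(k)]


def naive_rckmer(seq, k):
    freqs = dict(zip(all_kmers(k), naive_kmer(seq, k)))
    canon = sorted({min(w, revcomp(w)) for w in all_kmers(k)})
    out = {c: 0.0 for c in canon}
    for w, f in freqs.items():
        out[min(w, revcomp(w))] += f
    return [out[c] for c in canon]


def naive_enac(seq, window, step=1):
    out = []
    for start in range(0, len(seq) - window + 1, step):
        chunk = seq[start : start + window]
        for nt in "ACGT":
            out.append(chunk.count(nt) / window)
    return out


def naive_cksnap(seq, k_set=(0, 1, 2, 3, 4, 5)):
    out = []
    for k in sorted(k_set):
        pairs = {p: 0 for p in all_kmers(2)}
        n = len(seq) - k - 1
        for i in range(n):
            pairs[seq[i] + seq[i + k + 1]] += 1
        for p in all_kmers(2):
            out.append(pairs[p] / n)
    return out


def naive_ncp(seq):
    out = []
    for c in seq:
        out.extend(NCP[c])
    return out


def naive_anf(seq):
    out = []
    for i, c in enumerate(seq, start=1):
        out.extend(NCP[c])
        out.append(seq[:i].count(c) / i)
    return out


def naive_eiip(seq):
    return [EIIP[c] for c in seq]


def naive_pseeiip(seq):
    tri = all_kmers(3)
    counts = {t: 0 for t in tri}
    n = len(seq) - 2
    for i in range(n):
        counts[seq[i : i + 3]] += 1
    return [sum(EIIP[c] for c in t) * counts[t] / n for t in tri]


def naive_onehot(seq):
    out = []
    for c in seq:
        out.extend(ONEHOT[c])
    return out
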