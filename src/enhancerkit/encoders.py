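"""Nine DNA composition encoders mapping sequences to named feature vectors.

Every encoder takes a list of validated records and returns a
:class:`FeatureMatrix` — one row per record, deterministic column order
(lexicographic with A < C < G < T throughout), no NaN/inf. The schemes:

k-mer
    Frequency of each length-k word over the ``L - k + 1`` sliding windows.
RCK-mer
    k-mer after collapsing each word with its reverse complement into one
    canonical feature (lexicographic minimum of the pair); a dinucleotide
    alphabet collapses from 16 to 10 features.
ENAC
    Per-window nucleotide composition along a fixed-length window slid
    5'→3' over uniform-length sequences.
CKSNAP
    Frequencies of ordered nucleotide pairs separated by exactly k
    positions, for each k in a gap set; the pair count for gap k is
    ``L - k - 1``. Gap 0 coincides with the 2-mer encoding.
NCP
    Fixed chemical-property triple per nucleotide: A=(1,1,1), C=(0,1,0),
    G=(1,0,0), T=(0,0,1) (ring structure, hydrogen bonding, functional
    group).
ANF
    Per position, the NCP triple plus the accumulated frequency of that
    position's nucleotide in the prefix 1..i, divided by i.
EIIP
    Electron-ion interaction pseudopotential per nucleotide: A 0.1260,
    C 0.1340, G 0.0806, T 0.1335; one column per position.
PseEIIP
    64 trinucleotide features: (EIIP_a + EIIP_b + EIIP_c) times the
    trinucleotide's sliding-window frequency.
One-Hot
    A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1] per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from types import MappingProxyType
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord

#: Electron-ion interaction pseudopotential of each nucleotide.
EIIP_TABLE = MappingProxyType({"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335})

#: Chemical-property triple (ring structure, hydrogen bond, functional group).
NCP_TABLE = MappingProxyType(
    {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "T": (0, 0, 1)}
)

ONEHOT_TABLE = MappingProxyType(
    {"A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1)}
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_NT = "ACGT"
_CODE = {c: i for i, c in enumerate(_NT)}


class EncodingError(ValueError):
    """Raised when records violate an encoder's length preconditions."""


@dataclass
class FeatureMatrix:
    """Named-column numeric matrix, one row per input record."""

    feature_names: list[str]
    values: np.ndarray
    record_ids: list[str]
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.record_ids) != n or len(self.feature_names) != p:
            raise ValueError("shape mismatch between values, ids and names")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.record_ids, columns=self.feature_names
        )

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order."""
        idx = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"unknown feature names: {missing[:5]}")
        cols = [idx[n] for n in names]
        return FeatureMatrix(
            list(names), self.values[:, cols], list(self.record_ids), self.tag
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)

    @classmethod
    def from_csv(cls, path, tag: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(float), [str(i) for i in df.index], tag)


def _seqs(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    records = list(records)
    if not records:
        raise EncodingError("no records to encode")
    return records


def _uniform_length(records: list[SequenceRecord], scheme: str) -> int:
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise EncodingError(
            f"{scheme} requires uniform-length sequences; saw lengths {sorted(lengths)}"
        )
    return lengths.pop()


def _seq_codes(seq: str) -> np.ndarray:
    """Map ACGT to 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    return lut[arr]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each length-k window (base-4, first base most significant)."""
    out = np.zeros(codes.size - k + 1, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : codes.size - k + 1 + j]
    return out


def kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in product(_NT, repeat=k)]


def encode_kmer(records: Iterable[SequenceRecord], k: int) -> FeatureMatrix:
    """Sliding-window k-mer frequencies; 4**k columns, rows sum to 1."""
    if not 1 <= k <= 8:
        raise ValueError("k must be a small positive integer")
    records = _seqs(records)
    names = kmer_names(k)
    rows = np.zeros((len(records), 4**k))
    for i, r in enumerate(records):
        if len(r) < k:
            raise EncodingError(f"record {r.id!r}: length {len(r)} < k={k}")
        codes = _window_codes(_seq_codes(r.seq), k)
        counts = np.bincount(codes, minlength=4**k)
        rows[i] = counts / codes.size
    return FeatureMatrix(names, rows, [r.id for r in records], tag=f"kmer{k}")


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def rc_canonical_kmers(k: int) -> list[str]:
    """Canonical (lexicographic-minimum) representative of each RC pair."""
    return sorted(
        {min(w, reverse_complement(w)) for w in kmer_names(k)}
    )


def encode_rckmer(records: Iterable[SequenceRecord], k: int) -> FeatureMatrix:
    """Reverse-complement-collapsed k-mer frequencies.

    Each k-mer and its reverse complement share one canonical column whose
    value is the summed frequency of both (self-complementary words counted
    once); rows still sum to 1.
    """
    base = encode_kmer(records, k)
    canon = rc_canonical_kmers(k)
    col = {name: i for i, name in enumerate(canon)}
    rows = np.zeros((base.values.shape[0], len(canon)))
    for j, word in enumerate(kmer_names(k)):
        rows[:, col[min(word, reverse_complement(word))]] += base.values[:, j]
    return FeatureMatrix(canon, rows, list(base.record_ids), tag=f"rckmer{k}")


def encode_enac(
    records: Iterable[SequenceRecord], window: int = 5, step: int = 1
) -> FeatureMatrix:
    """Per-window nucleotide composition over a sliding window."""
    records = _seqs(records)
    L = _uniform_length(records, "ENAC")
    if window < 1 or window > L:
        raise EncodingError(f"ENAC window {window} invalid for length {L}")
    starts = range(0, L - window + 1, step)
    names = [f"win{s + 1}_{nt}" for s in starts for nt in _NT]
    rows = np.zeros((len(records), len(names)))
    for i, r in enumerate(records):
        codes = _seq_codes(r.seq)
        for b, s in enumerate(starts):
            counts = np.bincount(codes[s : s + window], minlength=4)
            rows[i, 4 * b : 4 * b + 4] = counts / window
    return FeatureMatrix(names, rows, [r.id for r in records], tag=f"enac{window}")


def encode_cksnap(
    records: Iterable[SequenceRecord], k_set: Sequence[int] = (0, 1, 2, 3, 4, 5)
) -> FeatureMatrix:
    """Composition of k-spaced nucleotide pairs for each gap in ``k_set``.

    For gap k there are ``L - k - 1`` ordered pairs (a, b) with b exactly k
    positions after a; each 16-column block is that gap's pair frequency
    distribution. Gap 0 reproduces the 2-mer encoding.
    """
    records = _seqs(records)
    k_set = sorted(set(int(k) for k in k_set))
    if any(k < 0 for k in k_set) or not k_set:
        raise EncodingError("gap set must be non-empty and non-negative")
    pairs = kmer_names(2)
    names = [f"gap{k}_{p}" for k in k_set for p in pairs]
    rows = np.zeros((len(records), len(names)))
    for i, r in enumerate(records):
        L = len(r)
        if L < max(k_set) + 2:
            raise EncodingError(
                f"record {r.id!r}: length {L} too short for gap {max(k_set)}"
            )
        codes = _seq_codes(r.seq)
        for b, k in enumerate(k_set):
            first = codes[: L - k - 1]
            second = codes[k + 1 :]
            counts = np.bincount(first * 4 + second, minlength=16)
            rows[i, 16 * b : 16 * b + 16] = counts / (L - k - 1)
    return FeatureMatrix(names, rows, [r.id for r in records], tag="cksnap")


def encode_ncp(records: Iterable[SequenceRecord]) -> FeatureMatrix:
    """Positionwise chemical-property triples; 3L binary columns."""
    records = _seqs(records)
    L = _uniform_length(records, "NCP")
    table = np.array([NCP_TABLE[nt] for nt in _NT], dtype=float)
    names = [f"pos{i + 1}_c{c + 1}" for i in range(L) for c in range(3)]
    rows = np.stack([table[_seq_codes(r.seq)].ravel() for r in records])
    return FeatureMatrix(names, rows, [r.id for r in records], tag="ncp")


def encode_anf(records: Iterable[SequenceRecord]) -> FeatureMatrix:
    """NCP triple plus accumulated nucleotide frequency per position.

    The fourth channel at position i (1-based) is the count of that
    position's nucleotide within positions 1..i, divided by i.
    """
    records = _seqs(records)
    L = _uniform_length(records, "ANF")
    table = np.array([NCP_TABLE[nt] for nt in _NT], dtype=float)
    names = [
        f"pos{i + 1}_{ch}" for i in range(L) for ch in ("c1", "c2", "c3", "anf")
    ]
    rows = np.zeros((len(records), 4 * L))
    positions = np.arange(1, L + 1)
    for r_i, r in enumerate(records):
        codes = _seq_codes(r.seq)
        ncp = table[codes]
        # running count of each position's own nucleotide within the prefix
        onehot = np.zeros((L, 4))
        onehot[np.arange(L), codes] = 1.0
        running = np.cumsum(onehot, axis=0)[np.arange(L), codes]
        block = np.concatenate([ncp, (running / positions)[:, None]], axis=1)
        rows[r_i] = block.ravel()
    return FeatureMatrix(names, rows, [r.id for r in records], tag="anf")


def encode_eiip(records: Iterable[SequenceRecord]) -> FeatureMatrix:
    """Per-position electron-ion interaction pseudopotential; L columns."""
    records = _seqs(records)
    L = _uniform_length(records, "EIIP")
    table = np.array([EIIP_TABLE[nt] for nt in _NT])
    names = [f"pos{i + 1}" for i in range(L)]
    rows = np.stack([table[_seq_codes(r.seq)] for r in records])
    return FeatureMatrix(names, rows, [r.id for r in records], tag="eiip")


def encode_pseeiip(records: Iterable[SequenceRecord]) -> FeatureMatrix:
    """Trinucleotide pseudopotential: summed EIIP of the three bases times
    the trinucleotide's sliding-window frequency; 64 columns."""
    records = _seqs(records)
    tri = kmer_names(3)
    eiip_sum = np.array([sum(EIIP_TABLE[c] for c in t) for t in tri])
    rows = np.zeros((len(records), 64))
    for i, r in enumerate(records):
        if len(r) < 3:
            raise EncodingError(f"record {r.id!r}: length {len(r)} < 3")
        codes = _window_codes(_seq_codes(r.seq), 3)
        freq = np.bincount(codes, minlength=64) / codes.size
        rows[i] = eiip_sum * freq
    return FeatureMatrix(tri, rows, [r.id for r in records], tag="pseeiip")


def encode_onehot(records: Iterable[SequenceRecord]) -> FeatureMatrix:
    """Positionwise one-hot encoding; 4L binary columns."""
    records = _seqs(records)
    L = _uniform_length(records, "One-Hot")
    table = np.array([ONEHOT_TABLE[nt] for nt in _NT], dtype=float)
    names = [f"pos{i + 1}_{nt}" for i in range(L) for nt in _NT]
    rows = np.stack([table[_seq_codes(r.seq)].ravel() for r in records])
    return FeatureMatrix(names, rows, [r.id for r in records], tag="onehot")


def merge_matrices(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation; names prefixed by each matrix's tag."""
    if not matrices:
        raise ValueError("nothing to merge")
    ids = matrices[0].record_ids
    for m in matrices[1:]:
        if m.record_ids != ids:
            raise ValueError("record ids/order differ between matrices")
    names: list[str] = []
    for i, m in enumerate(matrices):
        tag = m.tag or f"m{i}"
        names.extend(f"{tag}.{n}" for n in m.feature_names)
    values = np.concatenate([m.values for m in matrices], axis=1)
    return FeatureMatrix(names, values, list(ids), tag="merged")


#: Encoder registry for the CLI and pipelines.
ENCODERS: dict[str, Callable[..., FeatureMatrix]] = {
    "kmer": encode_kmer,
    "rckmer": encode_rckmer,
    "enac": encode_enac,
    "cksnap": encode_cksnap,
    "ncp": encode_ncp,
    "anf": encode_anf,
    "eiip": encode_eiip,
    "pseeiip": encode_pseeiip,
    "onehot": encode_onehot,
}


def default_identification_encoders() -> list[tuple[str, dict]]:
    """The seven schemes retained for enhancer identification: 2-/3-/4-mer,
    CKSNAP, ENAC, PseEIIP and RCK-mer."""
    return [
        ("kmer", {"k": 2}),
        ("kmer", {"k": 3}),
        ("kmer", {"k": 4}),
        ("cksnap", {}),
        ("enac", {}),
        ("pseeiip", {}),
        ("rckmer", {"k": 4}),
    ]
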