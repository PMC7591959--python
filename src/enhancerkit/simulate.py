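"""Synthetic labeled benchmark generator with planted enhancer-like signal.

Real enhancer benchmarks are fixed-length genomic fragments (200 bp in the
classic Liu et al. set) split into a positive and a matched negative class.
This module emulates that structure: both classes are i.i.d. per-position
backgrounds with a controllable GC fraction, and the positive class
additionally carries short planted motifs. Composition signal (gc_pos vs
gc_neg) and motif signal (motifs, motif_prob) are independently tunable so
downstream encoders, selectors and classifiers can be exercised at any
signal strength, including the exact null (no motif, equal GC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabeledDataset, SequenceRecord

_NT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-class sequence dataset.

    gc_pos / gc_neg are the background GC fractions per class; each motif is
    planted in a positive sequence with probability ``motif_prob``,
    overwriting the background at a uniform random position so sequence
    length never changes.
    """

    n_pos: int = 100
    n_neg: int = 100
    length: int = 200
    motifs: list[str] = field(default_factory=list)
    motif_prob: float = 1.0
    gc_pos: float = 0.5
    gc_neg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.motif_prob <= 1.0):
            raise ValueError("motif_prob must be in [0, 1]")
        for gc in (self.gc_pos, self.gc_neg):
            if not (0.0 < gc < 1.0):
                raise ValueError("GC fractions must lie strictly in (0, 1)")
        for m in self.motifs:
            if set(m) - set("ACGT") or not m:
                raise ValueError(f"motif {m!r} is not a non-empty ACGT string")
            if len(m) > self.length:
                raise ValueError(
                    f"motif {m!r} longer than sequence length {self.length}"
                )


def _background(rng: np.random.Generator, n: int, length: int, gc: float) -> np.ndarray:
    # P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def _plant(rng: np.random.Generator, row: np.ndarray, motifs: list[str], prob: float) -> None:
    """Overwrite background with each motif at a random position.

    Placement avoids previously planted spans when possible (best effort:
    falls back to an arbitrary position if no free span remains).
    """
    length = row.size
    occupied: list[tuple[int, int]] = []
    for motif in motifs:
        if rng.random() >= prob:
            continue
        m = np.frombuffer(motif.encode(), dtype=np.uint8)
        codes = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), m)
        free = [
            s
            for s in range(length - len(motif) + 1)
            if all(s + len(motif) <= a or s >= b for a, b in occupied)
        ]
        start = int(rng.choice(free)) if free else int(rng.integers(0, length - len(motif) + 1))
        row[start : start + len(motif)] = codes
        occupied.append((start, start + len(motif)))


def generate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Generate a labeled dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pos = _background(rng, config.n_pos, config.length, config.gc_pos)
    for row in pos:
        _plant(rng, row, config.motifs, config.motif_prob)
    neg = _background(rng, config.n_neg, config.length, config.gc_neg)

    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    for i, row in enumerate(pos):
        rid = f"pos_{i:05d}"
        records.append(SequenceRecord(rid, "".join(_NT[row])))
        labels[rid] = 1
    for i, row in enumerate(neg):
        rid = f"neg_{i:05d}"
        records.append(SequenceRecord(rid, "".join(_NT[row])))
        labels[rid] = 0
    return LabeledDataset(records=records, labels=labels)


def two_tier_dataset(
    n_per_class: int = 100,
    length: int = 200,
    strong_motifs: tuple[str, ...] = ("ACGTACGT", "GGCCGGTA"),
    weak_motifs: tuple[str, ...] = ("ACGTACGT",),
    weak_prob: float = 0.6,
    seed: int = 0,
) -> LabeledDataset:
    """Strong-vs-weak signal tiers emulating strong/weak enhancer classes.

    Label 1 = strong tier (all motifs, always planted); label 0 = weak tier
    (fewer motifs, planted with probability ``weak_prob``). Strength is
    modelled purely as signal intensity, not as enhancer biology.
    """
    strong = generate_dataset(
        SimulationConfig(
            n_pos=n_per_class, n_neg=0, length=length,
            motifs=list(strong_motifs), motif_prob=1.0, seed=seed,
        )
    )
    weak = generate_dataset(
        SimulationConfig(
            n_pos=n_per_class, n_neg=0, length=length,
            motifs=list(weak_motifs), motif_prob=weak_prob, seed=seed + 1,
        )
    )
    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    for r in strong.records:
        rid = "strong_" + r.id
        records.append(SequenceRecord(rid, r.seq))
        labels[rid] = 1
    for r in weak.records:
        rid = "weak_" + r.id
        records.append(SequenceRecord(rid, r.seq))
        labels[rid] = 0
    return LabeledDataset(records=records, labels=labels)
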