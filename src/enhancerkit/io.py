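"""Reading, validating and writing DNA sequence data and binary labels.

Canonical in-memory representation for the whole toolkit: a list of
:class:`SequenceRecord` plus an id -> {0, 1} label map bundled into a
:class:`LabeledDataset`.  Sequences are uppercased on input; any character
outside {A, C, G, T} is either a hard error or drops the record, depending
on the chosen policy — the composition encoders all assume a strict
four-letter alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")

AmbiguousPolicy = Literal["error", "drop_record"]


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid sequence content."""


class LabelError(ValueError):
    """Raised when labels and records cannot be matched one-to-one."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence over the strict {A, C, G, T} alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be non-empty")
        if not self.seq:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FastaError(
                f"record {self.id!r}: non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Sequence records with a binary label per record id."""

    records: list[SequenceRecord]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LabelError(f"duplicate record ids: {dupes}")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise LabelError(f"records without labels: {missing}")
        orphans = sorted(set(self.labels) - set(ids))
        if orphans:
            raise LabelError(f"labels without records: {orphans}")
        bad = {i: v for i, v in self.labels.items() if v not in (0, 1)}
        if bad:
            raise LabelError(f"labels must be 0 or 1, got: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def y(self) -> list[int]:
        """Labels in record order."""
        return [self.labels[r.id] for r in self.records]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]


def read_fasta(
    path: str | Path, ambiguous_policy: AmbiguousPolicy = "error"
) -> list[SequenceRecord]:
    """Read a FASTA file into validated, uppercased records.

    Parameters
    ----------
    path
        FASTA file with one or more records.
    ambiguous_policy
        ``"error"`` aborts on the first record containing a non-ACGT
        character (naming it); ``"drop_record"`` omits such records and
        logs how many were dropped.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FastaError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if set(seq) - ALPHABET or not seq:
            if ambiguous_policy == "drop_record":
                dropped += 1
                continue
            bad = sorted(set(seq) - ALPHABET)
            raise FastaError(
                f"record {rid!r}: non-ACGT characters {bad} "
                "(use ambiguous_policy='drop_record' to skip)"
            )
        records.append(SequenceRecord(rid, seq))
    if dropped:
        logger.warning("dropped %d record(s) with non-ACGT characters", dropped)
    return records


def _check_fasta_shape(path: Path) -> None:
    """Reject sequence data appearing before the first '>' header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno} contains sequence data "
                    "before the first FASTA header"
                )
            return


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (60-column sequence lines)."""
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def read_labels(
    path: str | Path, records: list[SequenceRecord]
) -> LabeledDataset:
    """Match a two-column TSV (id, label in {0,1}) to records.

    Every record must have exactly one label and vice versa; offenders are
    listed in the error. Record order is preserved.
    """
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            rid, raw = parts[0].strip(), parts[1].strip()
            if raw not in ("0", "1"):
                raise LabelError(
                    f"{path}: line {lineno}: label for {rid!r} must be "
                    f"0 or 1, got {raw!r}"
                )
            if rid in labels:
                raise LabelError(f"{path}: duplicate label for id {rid!r}")
            labels[rid] = int(raw)
    return LabeledDataset(records=list(records), labels=labels)


def labels_from_headers(records: list[SequenceRecord]) -> LabeledDataset:
    """Parse labels from an ``id|label`` header convention.

    Accepts ids of the form ``name|1`` / ``name|0``; the suffix is stripped
    from the stored id. TSV label files remain the canonical path.
    """
    out: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    for r in records:
        base, sep, suffix = r.id.rpartition("|")
        if not sep or suffix not in ("0", "1"):
            raise LabelError(
                f"record {r.id!r}: header does not end in '|0' or '|1'"
            )
        out.append(SequenceRecord(base, r.seq))
        labels[base] = int(suffix)
    return LabeledDataset(records=out, labels=labels)


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Write labels as a two-column TSV in record order."""
    with open(path, "w") as fh:
        for r in dataset.records:
            fh.write(f"{r.id}\t{dataset.labels[r.id]}\n")
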