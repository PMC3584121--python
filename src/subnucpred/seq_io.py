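"""Reading and validation of protein sequences and localization labels.

Sequences arrive as plain FASTA; class labels arrive in a sidecar TSV
(``id<TAB>label1[,label2...]``).  A protein may carry several localization
labels (multi-localization); training code uses only single-label records,
multi-label records are reserved for the any-match evaluation criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)

#: Ambiguity handling in ``clean`` mode: B/Z/U/J map to a concrete residue,
#: X, O, stop codons and gap characters are dropped.
_CLEAN_MAP = {"B": "D", "Z": "E", "U": "C", "J": "L"}
_CLEAN_DROP = set("XO*-.")


class SequenceValidationError(ValueError):
    """Raised when a raw sequence cannot be validated."""


class DatasetError(ValueError):
    """Raised when FASTA and label files cannot be assembled into a dataset."""


@dataclass
class SequenceRecord:
    """A validated protein sequence with zero or more localization labels."""

    id: str
    sequence: str
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = [i for i, ch in enumerate(self.sequence) if ch not in _STANDARD_SET]
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residues at positions {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of records plus the ordered list of classes."""

    records: list[SequenceRecord]
    classes: list[str]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise DatasetError("duplicate record ids in dataset")
        present = set().union(*(r.labels for r in self.records)) if self.records else set()
        if not present <= set(self.classes):
            raise DatasetError(f"labels {present - set(self.classes)} missing from class list")

    def __len__(self) -> int:
        return len(self.records)

    def single_label_subset(self) -> "Dataset":
        """Records with exactly one label (the training population)."""
        recs = [r for r in self.records if len(r.labels) == 1]
        return Dataset(recs, list(self.classes))


def validate_sequence(raw: str, policy: str = "clean") -> str:
    """Validate/sanitize a raw amino-acid string.

    ``strict``: any character outside the 20 standard residues is an error.
    ``clean``: B->D, Z->E, U->C, J->L; X, O, '*' and gap characters dropped.
    Lower-case input is accepted and upper-cased first.  Idempotent.
    """
    if not raw:
        raise SequenceValidationError("empty sequence")
    if policy not in ("strict", "clean"):
        raise ValueError(f"unknown policy {policy!r}")
    s = raw.upper()
    if policy == "strict":
        bad = [i for i, ch in enumerate(s) if ch not in _STANDARD_SET]
        if bad:
            raise SequenceValidationError(f"non-standard residues at positions {bad}")
        return s
    out = []
    for ch in s:
        if ch in _STANDARD_SET:
            out.append(ch)
        elif ch in _CLEAN_MAP:
            out.append(_CLEAN_MAP[ch])
        elif ch in _CLEAN_DROP or ch.isspace():
            continue
        else:
            raise SequenceValidationError(f"unrecognized character {ch!r}")
    if not out:
        raise SequenceValidationError("sequence empty after cleaning")
    return "".join(out)


def read_fasta(path: str | Path, policy: str = "clean") -> list[SequenceRecord]:
    """Read a FASTA file into validated records (file order preserved).

    The first whitespace-delimited token of each header is the record id.
    An empty file yields an empty list.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            return []
        if first != ">":
            raise DatasetError(f"{path}: not FASTA (line 1 does not start with '>')")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(SequenceRecord(rec.id, validate_sequence(str(rec.seq), policy)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta` on valid input)."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse the sidecar label TSV into ``id -> set of labels``."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(f"{path}:{lineno}: expected 'id<TAB>labels'")
            rid, labels = parts
            if rid in out:
                raise DatasetError(f"{path}:{lineno}: duplicate id {rid!r}")
            out[rid] = frozenset(x.strip() for x in labels.split(",") if x.strip())
    return out


def load_dataset(fasta: str | Path, labels: str | Path, policy: str = "clean") -> Dataset:
    """Assemble a labeled dataset from a FASTA file and a label TSV.

    Every FASTA id must appear in the label file; class order is the order of
    first appearance over records, so it is independent of label-file order.
    """
    records = read_fasta(fasta, policy)
    label_map = read_labels(labels)
    missing = [r.id for r in records if r.id not in label_map]
    if missing:
        raise DatasetError(f"ids missing from label file: {missing}")
    labeled = [SequenceRecord(r.id, r.sequence, label_map[r.id]) for r in records]
    classes: list[str] = []
    for r in labeled:
        for lab in sorted(r.labels):
            if lab not in classes:
                classes.append(lab)
    return Dataset(labeled, classes)
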