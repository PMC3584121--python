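"""Per-residue physicochemical property tables and pair distance matrices.

The packaged default table holds 29 unique AAindex1 scales (exported from
the AAindex snapshot shipped with seqinr 4.2-36); one accession
(PONP800106) is counted twice in the default 30-slot list used by the
autocorrelation/autocovariance extractors, so their 30-properties-by-30-lags
feature contract holds.  Users may supply a full AAindex1 flat file for the
larger property set.

Two amino-acid pair distance matrices back the sequence-order descriptors:
the Grantham chemical distance (reconstructed from its defining formula)
and a clearly-labelled synthetic stand-in for the Schneider-Wrede
physicochemical distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seq_io import STANDARD_RESIDUES, SequenceRecord

_RESIDUE_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


class PropertyError(KeyError):
    pass


@dataclass
class PropertyTable:
    """Named per-residue numeric scales (20 finite values each)."""

    entries: dict[str, np.ndarray]  # accession -> values in STANDARD_RESIDUES order
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, v in self.entries.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (20,) or not np.all(np.isfinite(v)):
                raise ValueError(f"property {name}: needs exactly 20 finite values")
            self.entries[name] = v

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def values(self, name: str) -> np.ndarray:
        try:
            return self.entries[name]
        except KeyError:
            raise PropertyError(f"unknown property {name!r}") from None


@dataclass
class ResidueSignal:
    """A sequence encoded as a numeric signal under one property scale."""

    values: np.ndarray
    source_property: str
    standardized: bool

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PairDistanceMatrix:
    """A 20x20 nonnegative residue pair distance (zero diagonal enforced)."""

    name: str
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (20, 20) or not np.all(np.isfinite(d)):
            raise ValueError("distance matrix must be 20x20 finite")
        np.fill_diagonal(d, 0.0)
        self.d = d

    def distance(self, a: str, b: str) -> float:
        return float(self.d[_RESIDUE_INDEX[a], _RESIDUE_INDEX[b]])


def _read_property_tsv(text: str, provenance: str) -> PropertyTable:
    entries: dict[str, np.ndarray] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            assert "".join(header[2:]) == STANDARD_RESIDUES
            continue
        entries[parts[0]] = np.array([float(x) for x in parts[2:]])
    return PropertyTable(entries, provenance)


def load_property_table() -> PropertyTable:
    """The packaged 29-accession property table."""
    text = resources.files("subnucpred.data").joinpath("physchem_properties.tsv").read_text()
    return _read_property_tsv(text, "packaged AAindex1 subset (seqinr 4.2-36 snapshot)")


#: The default 30-slot property list for the lag-based extractors.  The
#: duplicated accession mirrors the source table's double listing; the second
#: occurrence is disambiguated as ``PONP800106#2`` in feature names.
TABLE_SLOTS: tuple[str, ...] = (
    "BULH740101", "BULH740102", "PONP800106", "PONP800104", "PONP800105",
    "PONP800106#2", "MANP780101", "EISD840101", "JOND750101", "HOPT810101",
    "PARJ860101", "JANJ780101", "PONP800107", "CHOC760102", "ROSG850101",
    "ROSG850102", "BHAR880101", "KARP850101", "KARP850102", "KARP850103",
    "JANJ780102", "JANJ780103", "LEVM780101", "LEVM780102", "LEVM780103",
    "GRAR740102", "GRAR740103", "MCMT640101", "PONP800108", "KYTJ820101",
)


def resolve_slot(name: str) -> str:
    """Strip the duplicate-slot suffix, yielding a real accession."""
    return name.split("#")[0]


def standardize_property(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd rescaling over the 20 residues (population sd).

    Idempotent; a constant scale (sd = 0) is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (20,):
        raise ValueError("expected 20 residue values")
    sd = v.std()  # population convention, divisor 20
    if sd == 0:
        raise ValueError("constant property cannot be standardized")
    return (v - v.mean()) / sd


def encode_signal(
    seq: SequenceRecord | str,
    prop: str,
    table: PropertyTable | None = None,
    standardized: bool = True,
) -> ResidueSignal:
    """Encode a sequence as the per-position (standardized) property value."""
    if table is None:
        table = load_property_table()
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    v = table.values(resolve_slot(prop))
    if standardized:
        v = standardize_property(v)
    idx = np.fromiter((_RESIDUE_INDEX[ch] for ch in s), dtype=int, count=len(s))
    return ResidueSignal(v[idx], prop, standardized)


def _read_matrix_tsv(text: str, name: str) -> PairDistanceMatrix:
    rows: dict[str, list[float]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    d = np.zeros((20, 20))
    for i, a in enumerate(STANDARD_RESIDUES):
        for j, b in enumerate(STANDARD_RESIDUES):
            d[i, j] = rows[a][header.index(b)]
    return PairDistanceMatrix(name, d)


_MATRIX_FILES = {
    "grantham": "grantham.tsv",
    "schneider-wrede": "schneider_wrede_synthetic.tsv",
}


def get_distance_matrix(name: str) -> PairDistanceMatrix:
    """Load a packaged pair distance matrix by name.

    ``schneider-wrede`` resolves to the packaged synthetic stand-in (see
    module docstring); values are preserved as stored (directional matrices
    would be accepted as-is).
    """
    try:
        fname = _MATRIX_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown matrix {name!r}; available: {', '.join(_MATRIX_FILES)}"
        ) from None
    text = resources.files("subnucpred.data").joinpath(fname).read_text()
    return _read_matrix_tsv(text, name)


def read_aaindex1(path: str | Path) -> PropertyTable:
    """Read a user-supplied AAindex1 flat file (H/I record layout).

    Entries with missing values (``NA``) are skipped.  The I record lists
    values for A/R/N/D/C/Q/E/G/H/I then L/K/M/F/P/S/T/W/Y/V.
    """
    aaindex_order = "ARNDCQEGHILKMFPSTWYV"
    perm = [aaindex_order.index(r) for r in STANDARD_RESIDUES]
    entries: dict[str, np.ndarray] = {}
    acc: str | None = None
    collecting = 0
    vals: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("H "):
            acc = line.split()[1]
        elif line.startswith("I "):
            collecting = 2
            vals = []
        elif collecting:
            vals.extend(line.split())
            collecting -= 1
            if collecting == 0 and acc is not None:
                if "NA" not in vals and len(vals) == 20:
                    v = np.array([float(x) for x in vals])
                    entries[acc] = v[perm]
    return PropertyTable(entries, f"user AAindex1 file {path}")
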