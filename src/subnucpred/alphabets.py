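"""Reduced amino-acid alphabets.

Each classification scheme partitions the 20 standard residues into k
groups (hydrophobic/polar, charge classes, structural classes, ...).  A
protein sequence re-expressed over such an alphabet becomes a symbol
sequence of the same length, the substrate for the composition, global
descriptor and Lempel-Ziv extractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .seq_io import STANDARD_RESIDUES, SequenceRecord

_STANDARD_SET = frozenset(STANDARD_RESIDUES)


@dataclass(frozen=True)
class ClassificationScheme:
    """A named partition of the 20 residues into ordered groups.

    Symbol numbering follows the left-to-right group order, 1-based.
    """

    name: str
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        union: set[str] = set()
        for g in self.groups:
            if union & g:
                raise ValueError(f"scheme {self.name}: groups overlap on {union & g}")
            union |= g
        if union != _STANDARD_SET:
            raise ValueError(
                f"scheme {self.name}: groups do not cover the standard alphabet "
                f"(missing {_STANDARD_SET - union}, extra {union - _STANDARD_SET})"
            )

    @property
    def k(self) -> int:
        return len(self.groups)

    def symbol_of(self, residue: str) -> int:
        for i, g in enumerate(self.groups, 1):
            if residue in g:
                return i
        raise KeyError(residue)


@dataclass(frozen=True)
class SymbolSequence:
    """A sequence of group indices (1..k) under a scheme."""

    symbols: tuple[int, ...]
    scheme: ClassificationScheme

    def __len__(self) -> int:
        return len(self.symbols)


def _load_schemes() -> dict[str, ClassificationScheme]:
    out: dict[str, ClassificationScheme] = {}
    text = resources.files("subnucpred.data").joinpath("classification_schemes.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, k, groups = line.split("\t")
        scheme = ClassificationScheme(name, tuple(frozenset(g) for g in groups.split("|")))
        if scheme.k != int(k):
            raise ValueError(f"scheme {name}: declared k={k}, parsed {scheme.k} groups")
        out[name] = scheme
    return out


_SCHEMES: dict[str, ClassificationScheme] = _load_schemes()

#: Scheme names in packaged order.
SCHEME_NAMES: tuple[str, ...] = tuple(_SCHEMES)

#: Default subset for the quadratically-growing dipeptide extractor.
LDC_DEFAULT_SCHEMES: tuple[str, ...] = ("HP", "DHP", "7-Cat", "ms", "lesk", "Murphy8")


def get_scheme(name: str) -> ClassificationScheme:
    """Return a packaged scheme by name."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown scheme {name!r}; available: {', '.join(SCHEME_NAMES)}") from None


def list_schemes(names: str | list[str] | None = None) -> list[ClassificationScheme]:
    """Resolve a name list, ``"all"`` or None to scheme objects."""
    if names is None or names == "all":
        return [_SCHEMES[n] for n in SCHEME_NAMES]
    if isinstance(names, str):
        names = [names]
    return [get_scheme(n) for n in names]


def reduce_sequence(seq: SequenceRecord | str, scheme: ClassificationScheme) -> SymbolSequence:
    """Map a protein sequence position-wise onto its reduced alphabet."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    lut = {}
    for i, g in enumerate(scheme.groups, 1):
        for r in g:
            lut[r] = i
    return SymbolSequence(tuple(lut[ch] for ch in s), scheme)
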