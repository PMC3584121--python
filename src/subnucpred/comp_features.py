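"""Classification-based feature extractors.

All four extractors operate on a sequence re-expressed over a reduced
amino-acid alphabet:

* LAAC — local composition of the k symbols over an N-terminal window
  (default 60 residues) and a C-terminal window (default 15), a fixed-position
  proxy for targeting-signal content.
* LDC — local dipeptide (ordered adjacent symbol pair) composition over the
  same two windows.
* GD — Dubchak's global descriptor: composition, transition and distribution
  of each symbol along the whole sequence.
* LZC — Lempel-Ziv complexity of the reduced sequence, the component count of
  its exhaustive copy-or-generate synthesis history.

Windows shorter than the sequence are truncated, never padded; output
dimensionality depends only on the scheme and parameters, never on content.
"""

from __future__ import annotations

import math

import numpy as np

from .alphabets import ClassificationScheme, SymbolSequence, list_schemes, reduce_sequence
from .feature_block import FeatureBlock, concat_blocks
from .seq_io import SequenceRecord


def _symbols(seq: SequenceRecord | str, scheme: ClassificationScheme) -> tuple[int, ...]:
    return reduce_sequence(seq, scheme).symbols


def laac(
    seq: SequenceRecord | str,
    scheme: ClassificationScheme,
    n_window: int = 60,
    c_window: int = 15,
) -> FeatureBlock:
    """Local amino-acid composition over the N- and C-terminal windows.

    2k features; each window's k compositions sum to 1.
    """
    sym = _symbols(seq, scheme)
    if not sym:
        raise ValueError("empty sequence")
    k = scheme.k
    names, values = [], []
    for wname, window in (("N", sym[:n_window]), ("C", sym[-c_window:])):
        counts = np.bincount(window, minlength=k + 1)[1:]
        comp = counts / len(window)
        names += [f"LAAC[{scheme.name}]_{wname}_g{g}" for g in range(1, k + 1)]
        values.append(comp)
    return FeatureBlock(
        "laac", names, np.concatenate(values),
        {"scheme": scheme.name, "n_window": n_window, "c_window": c_window},
    )


def ldc(
    seq: SequenceRecord | str,
    scheme: ClassificationScheme,
    n_window: int = 60,
    c_window: int = 15,
) -> FeatureBlock:
    """Local dipeptide composition over the two terminal windows.

    2k^2 features (ordered pairs, self-pairs included), each window block
    normalized by its number of adjacencies.  A truncated window of length
    < 2 yields all-zero features for that window.
    """
    sym = _symbols(seq, scheme)
    if not sym:
        raise ValueError("empty sequence")
    k = scheme.k
    names, values = [], []
    for wname, window in (("N", sym[:n_window]), ("C", sym[-c_window:])):
        pair = np.zeros((k, k))
        if len(window) >= 2:
            a = np.asarray(window[:-1]) - 1
            b = np.asarray(window[1:]) - 1
            np.add.at(pair, (a, b), 1.0)
            pair /= len(window) - 1
        names += [
            f"LDC[{scheme.name}]_{wname}_g{i}g{j}"
            for i in range(1, k + 1) for j in range(1, k + 1)
        ]
        values.append(pair.ravel())
    return FeatureBlock(
        "ldc", names, np.concatenate(values),
        {"scheme": scheme.name, "n_window": n_window, "c_window": c_window},
    )


def global_descriptor(seq: SequenceRecord | str, scheme: ClassificationScheme) -> FeatureBlock:
    """Composition / transition / distribution global descriptor.

    k Comp + k(k-1)/2 Tran + 5k Dist features.  Tran counts unordered
    unequal adjacent symbol pairs over L-1 adjacencies.  Dist records the
    (1-based position / L) of the first, 25%, 50%, 75% and last occurrence
    of each symbol (ceil convention for the quartile occurrence index),
    zeros for absent symbols.
    """
    sym = np.asarray(_symbols(seq, scheme))
    if sym.size == 0:
        raise ValueError("empty sequence")
    k = scheme.k
    L = sym.size
    comp = np.bincount(sym, minlength=k + 1)[1:] / L

    tran = np.zeros((k, k))
    if L >= 2:
        a, b = sym[:-1] - 1, sym[1:] - 1
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        mask = lo != hi
        np.add.at(tran, (lo[mask], hi[mask]), 1.0)
        tran /= L - 1
    tran_vals = [tran[i, j] for i in range(k) for j in range(i + 1, k)]
    tran_names = [
        f"GD[{scheme.name}]_Tran_g{i + 1}g{j + 1}"
        for i in range(k) for j in range(i + 1, k)
    ]

    dist_vals, dist_names = [], []
    quarts = (0.25, 0.5, 0.75)
    for g in range(1, k + 1):
        pos = np.flatnonzero(sym == g) + 1  # 1-based
        if pos.size == 0:
            five = [0.0] * 5
        else:
            n = pos.size
            five = [pos[0] / L]
            five += [pos[max(math.ceil(q * n), 1) - 1] / L for q in quarts]
            five += [pos[-1] / L]
        dist_vals += five
        dist_names += [f"GD[{scheme.name}]_Dist_g{g}_{p}" for p in ("first", "q25", "q50", "q75", "last")]

    names = [f"GD[{scheme.name}]_Comp_g{g}" for g in range(1, k + 1)] + tran_names + dist_names
    values = np.concatenate([comp, tran_vals, dist_vals])
    return FeatureBlock("gd", names, values, {"scheme": scheme.name})


def lz_complexity(symbols: SymbolSequence | str | tuple[int, ...]) -> int:
    """Lempel-Ziv (1976) complexity: components of the exhaustive history.

    Each component extends the already-synthesized prefix by the longest
    copyable fragment plus one freshly generated symbol (the final component
    may be fully copyable).  An independent brute-force oracle that checks
    reproducibility step by step lives in the test suite.
    """
    if isinstance(symbols, SymbolSequence):
        s = symbols.symbols
    else:
        s = tuple(symbols)
    if len(s) == 0:
        raise ValueError("empty symbol sequence")
    return _lz_quadratic(s)


def _lz_quadratic(s: tuple[int, ...]) -> int:
    """Quadratic exhaustive-history construction by longest-copy search."""
    n = len(s)
    c = 0
    pos = 0
    while pos < n:
        # longest l such that s[pos:pos+l] occurs in s[0:pos+l-1]
        l = 0
        while pos + l < n:
            frag = s[pos : pos + l + 1]
            hay = s[: pos + l]  # prefix available while producing symbol pos+l
            if _contains(hay, frag):
                l += 1
            else:
                break
        comp_len = l + 1 if pos + l < n else l  # generate one new symbol unless at end
        pos += comp_len
        c += 1
    return c


def _contains(hay: tuple[int, ...], needle: tuple[int, ...]) -> bool:
    nlen = len(needle)
    return any(hay[i : i + nlen] == needle for i in range(len(hay) - nlen + 1))


def lzc_features(
    seq: SequenceRecord | str,
    schemes: str | list[str] | None = "all",
    normalize: bool = True,
) -> FeatureBlock:
    """One LZ-complexity feature per reduced alphabet.

    Default normalized by sequence length so mixed-length datasets do not
    confound complexity with length; set ``normalize=False`` for raw c(S).
    """
    scheme_objs = list_schemes(schemes)
    if not scheme_objs:
        raise ValueError("at least one scheme required")
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    L = len(s)
    names, values = [], []
    for sch in scheme_objs:
        c = lz_complexity(reduce_sequence(s, sch))
        names.append(f"LZC[{sch.name}]")
        values.append(c / L if normalize else float(c))
    return FeatureBlock("lzc", names, np.asarray(values), {"normalize": normalize})


def laac_all(seq, schemes="all", **kw) -> FeatureBlock:
    return concat_blocks([laac(seq, s, **kw) for s in list_schemes(schemes)], "laac")


def ldc_all(seq, schemes=None, **kw) -> FeatureBlock:
    from .alphabets import LDC_DEFAULT_SCHEMES

    schemes = LDC_DEFAULT_SCHEMES if schemes is None else schemes
    return concat_blocks([ldc(seq, s, **kw) for s in list_schemes(list(schemes))], "ldc")


def gd_all(seq, schemes="all") -> FeatureBlock:
    return concat_blocks([global_descriptor(seq, s) for s in list_schemes(schemes)], "gd")
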