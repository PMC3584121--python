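"""Property-based feature extractors.

Autocorrelation descriptors (normalized Moreau-Broto, Moran, Geary) probe
how a standardized residue property covaries with itself at sequence lags
1..30; sequence-order descriptors (coupling numbers and quasi-sequence-order)
summarize pair-distance structure under the Grantham and Schneider-Wrede
matrices; autocovariance is the classical Wold descriptor; the property
distribution descriptor (PPDD) histograms a 4-mer-smoothed, z-scored
property signal into 18 half-width bins with open tails.

Conventions for the degenerate constant signal: Moran, Geary and
autocovariance return 0, so homopolymeric stretches never abort a batch
extraction.
"""

from __future__ import annotations

import numpy as np

from .feature_block import FeatureBlock, concat_blocks
from .properties import (
    TABLE_SLOTS,
    PairDistanceMatrix,
    PropertyTable,
    ResidueSignal,
    encode_signal,
    get_distance_matrix,
    load_property_table,
    standardize_property,
    resolve_slot,
    _RESIDUE_INDEX,
)
from .seq_io import STANDARD_RESIDUES, SequenceRecord


def _sig(signal: ResidueSignal | np.ndarray) -> np.ndarray:
    return signal.values if isinstance(signal, ResidueSignal) else np.asarray(signal, float)


def _check_lag(n: int, d: int) -> None:
    if not 1 <= d <= n - 1:
        raise ValueError(f"lag {d} out of range for signal length {n} (need 1 <= d <= {n - 1})")


def moreau_broto(signal: ResidueSignal | np.ndarray, d: int) -> float:
    """Normalized Moreau-Broto autocorrelation at lag d:
    (1/(N-d)) * sum_i P(i) P(i+d) on the standardized property signal."""
    p = _sig(signal)
    n = len(p)
    _check_lag(n, d)
    return float(np.dot(p[:-d], p[d:]) / (n - d))


def moran(signal: ResidueSignal | np.ndarray, d: int) -> float:
    """Moran autocorrelation at lag d (sequence-level mean/variance; the
    variance denominator uses divisor N).  Constant signal -> 0."""
    p = _sig(signal)
    n = len(p)
    _check_lag(n, d)
    if p.max() == p.min():  # constant signal: variance is 0 by definition,
        return 0.0          # not merely by floating-point cancellation
    c = p - p.mean()
    var = np.dot(c, c) / n
    if var == 0:
        return 0.0
    return float((np.dot(c[:-d], c[d:]) / (n - d)) / var)


def geary(signal: ResidueSignal | np.ndarray, d: int) -> float:
    """Geary autocorrelation at lag d (denominator divisor N-1).
    Constant signal -> 0; always nonnegative."""
    p = _sig(signal)
    n = len(p)
    _check_lag(n, d)
    if p.max() == p.min():
        return 0.0
    c = p - p.mean()
    var = np.dot(c, c) / (n - 1)
    if var == 0:
        return 0.0
    num = np.sum((p[:-d] - p[d:]) ** 2) / (2 * (n - d))
    return float(num / var)


def autocovariance(signal: ResidueSignal | np.ndarray, d: int) -> float:
    """Wold autocovariance at lag d: (1/(N-d)) sum (P(i)-mean)(P(i+d)-mean)."""
    p = _sig(signal)
    n = len(p)
    _check_lag(n, d)
    if p.max() == p.min():
        return 0.0
    c = p - p.mean()
    return float(np.dot(c[:-d], c[d:]) / (n - d))


_AD_FUNCS = {"MB": moreau_broto, "Moran": moran, "Geary": geary}


def ad_features(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] = TABLE_SLOTS,
    max_lag: int = 30,
    table: PropertyTable | None = None,
) -> FeatureBlock:
    """The three autocorrelation descriptors over every property and lag.

    len(properties) x max_lag features per descriptor (900 with the default
    30-slot list), property-major then lag; 3x that in total.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if len(s) <= max_lag:
        raise ValueError(f"sequence length {len(s)} too short; need > {max_lag} residues")
    if table is None:
        table = load_property_table()
    names, values = [], []
    signals = {p: encode_signal(s, p, table, standardized=True).values for p in properties}
    for desc, fn in _AD_FUNCS.items():
        for p in properties:
            sig = signals[p]
            for d in range(1, max_lag + 1):
                names.append(f"AD-{desc}[{p}]_lag{d}")
                values.append(fn(sig, d))
    return FeatureBlock("ad", names, np.asarray(values), {"max_lag": max_lag})


def ac_features(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] = TABLE_SLOTS,
    max_lag: int = 30,
    table: PropertyTable | None = None,
) -> FeatureBlock:
    """Autocovariance over every property and lag (property-major)."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if len(s) <= max_lag:
        raise ValueError(f"sequence length {len(s)} too short; need > {max_lag} residues")
    if table is None:
        table = load_property_table()
    names, values = [], []
    for p in properties:
        sig = encode_signal(s, p, table, standardized=True).values
        for d in range(1, max_lag + 1):
            names.append(f"AC[{p}]_lag{d}")
            values.append(autocovariance(sig, d))
    return FeatureBlock("ac", names, np.asarray(values), {"max_lag": max_lag})


def coupling_number(seq: SequenceRecord | str, matrix: PairDistanceMatrix, j: int) -> float:
    """jth-rank sequence-order coupling number: sum of squared pair
    distances between residues j positions apart."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    n = len(s)
    if not 1 <= j <= n - 1:
        raise ValueError(f"rank {j} out of range for length {n}")
    idx = np.fromiter((_RESIDUE_INDEX[ch] for ch in s), dtype=int, count=n)
    return float(np.sum(matrix.d[idx[:-j], idx[j:]] ** 2))


def qso_descriptors(
    seq: SequenceRecord | str,
    matrices: tuple[PairDistanceMatrix, ...] | None = None,
    max_rank: int = 30,
    n_qso: int = 50,
    w: float = 0.1,
) -> FeatureBlock:
    """Sequence-order descriptors per distance matrix, concatenated.

    Per matrix: tau_1..tau_maxrank coupling numbers, then n_qso
    quasi-sequence-order values sharing the denominator
    sum_r f_r + w * sum_j tau_j — the first 20 are normalized residue
    frequencies, the remaining n_qso-20 are w*tau_j terms.  With the two
    default matrices and default ranks: 2*(30+50) = 160 features.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    n = len(s)
    if n <= max_rank:
        raise ValueError(f"sequence length {n} too short; need > {max_rank} residues")
    if matrices is None:
        matrices = (get_distance_matrix("grantham"), get_distance_matrix("schneider-wrede"))
    idx = np.fromiter((_RESIDUE_INDEX[ch] for ch in s), dtype=int, count=n)
    f = np.bincount(idx, minlength=20).astype(float)
    names, values = [], []
    for m in matrices:
        tau = np.array([np.sum(m.d[idx[:-j], idx[j:]] ** 2) for j in range(1, max_rank + 1)])
        denom = f.sum() + w * tau.sum()
        qso = np.concatenate([f / denom, w * tau[: n_qso - 20] / denom])
        names += [f"SD[{m.name}]_tau{j}" for j in range(1, max_rank + 1)]
        names += [f"SD[{m.name}]_X{r}" for r in range(1, n_qso + 1)]
        values.append(tau)
        values.append(qso)
    return FeatureBlock(
        "sd", names, np.concatenate(values),
        {"max_rank": max_rank, "n_qso": n_qso, "w": w},
    )


#: PPDD bin edges: open left tail below -4, sixteen half-width bins on
#: [-4, 4), open right tail — 18 bins total.
PPDD_EDGES = np.concatenate([[-np.inf], np.arange(-4.0, 4.5, 0.5), [np.inf]])


def ppdd(
    seq: SequenceRecord | str,
    prop: str,
    table: PropertyTable | None = None,
) -> FeatureBlock:
    """Physicochemical property distribution descriptor (18 bin frequencies).

    Encode with the raw property, average over all overlapping 4-mers,
    z-score against the property's theoretical mean/sd over the 20 residues,
    then histogram into the 18 bins.  Frequencies sum to 1.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if len(s) < 4:
        raise ValueError("sequence shorter than 4 residues")
    if table is None:
        table = load_property_table()
    raw = encode_signal(s, prop, table, standardized=False).values
    kern = np.convolve(raw, np.full(4, 0.25), mode="valid")  # N-3 overlapping 4-mer means
    v = table.values(resolve_slot(prop))
    mu, sd = v.mean(), v.std()
    if sd == 0:
        raise ValueError(f"property {prop}: constant scale")
    z = (kern - mu) / sd
    hist, _ = np.histogram(z, bins=PPDD_EDGES)
    freq = hist / len(z)
    names = [f"PPDD[{prop}]_bin{i}" for i in range(1, 19)]
    return FeatureBlock("ppdd", names, freq, {"property": prop})


def ppdd_all(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] | None = None,
    table: PropertyTable | None = None,
) -> FeatureBlock:
    if table is None:
        table = load_property_table()
    props = tuple(table.names()) if properties is None else properties
    return concat_blocks([ppdd(seq, p, table) for p in props], "ppdd")
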