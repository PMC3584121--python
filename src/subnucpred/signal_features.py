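"""Signal-analytic feature extractors on property-encoded sequences.

A protein sequence encoded under a physicochemical scale is treated as a
short nonstationary signal and summarized three ways:

* RQA — the signal is delay-embedded (m = 4, tau = 1), thresholded into a
  binary recurrence matrix at 20% of the mean pairwise distance, and
  quantified by 14 recurrence variables over its diagonal and vertical line
  structure (Webber/Marwan canonical set; l_min = v_min = 2; diagonal
  structures exclude the main diagonal, vertical structures include it).
* DWT — a 5-level bior3.1 wavelet decomposition; max/mean/min/sd of the
  coefficients at each scale (approximation + 5 details -> 24 features).
* HHT — empirical mode decomposition by cubic-spline-envelope sifting,
  per-IMF summary statistics, plus the Hilbert-Huang spectral entropy of the
  normalized marginal spectrum (0 = one spectral line, 1 = flat spectrum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as _hilbert

from .feature_block import FeatureBlock, concat_blocks
from .properties import PropertyTable, ResidueSignal, encode_signal, load_property_table
from .seq_io import SequenceRecord

logger = logging.getLogger(__name__)

RQA_VARIABLE_NAMES = (
    "RR", "DET", "meanL", "Lmax", "DIV", "ENTR_L",
    "LAM", "TT", "Vmax", "ENTR_V", "RATIO", "TREND", "T1", "T2",
)


def _values(signal) -> np.ndarray:
    return signal.values if isinstance(signal, ResidueSignal) else np.asarray(signal, float)


# --------------------------------------------------------------------------
# Recurrence quantification
# --------------------------------------------------------------------------

def embed(signal, m: int = 4, tau: int = 1) -> np.ndarray:
    """Delay-embed a signal: point i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = _values(signal)
    n = len(x)
    need = (m - 1) * tau + 1
    if n < need:
        raise ValueError(f"signal length {n} < minimum {need} for m={m}, tau={tau}")
    count = n - (m - 1) * tau
    return np.stack([x[j * tau : j * tau + count] for j in range(m)], axis=1)


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix (symmetric, unit main diagonal)."""

    matrix: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def recurrence_matrix(points: np.ndarray, radius_frac: float = 0.20) -> RecurrenceMatrix:
    """Threshold pairwise Euclidean distances at radius_frac x mean distance.

    The mean is over unordered point pairs (i < j).  If all points coincide
    the threshold is 0 and the matrix is all ones.
    """
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(pts), k=1)
    eps = radius_frac * dist[iu].mean()
    return RecurrenceMatrix((dist <= eps).astype(np.int8), float(eps))


def _runs(line: np.ndarray) -> list[int]:
    """Lengths of maximal runs of ones in a 0/1 vector."""
    out, cur = [], 0
    for v in line:
        if v:
            cur += 1
        elif cur:
            out.append(cur)
            cur = 0
    if cur:
        out.append(cur)
    return out


def _entropy(lengths: list[int]) -> float:
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def rqa_variables(rm: RecurrenceMatrix | np.ndarray, l_min: int = 2, v_min: int = 2) -> FeatureBlock:
    """The 14 recurrence variables of a binary recurrence matrix.

    Diagonal-line statistics (DET, meanL, Lmax, DIV, ENTR_L) exclude the
    main diagonal; vertical-line statistics (LAM, TT, Vmax, ENTR_V) include
    it.  TREND is the least-squares slope of the recurrence density of the
    k-th diagonal against k.  T1/T2 are the mean vertical recurrence times
    (all points / run starts).  Degenerate denominators yield 0.
    """
    R = rm.matrix if isinstance(rm, RecurrenceMatrix) else np.asarray(rm)
    n = R.shape[0]
    rr = R.sum() / n ** 2

    diag_lines: list[int] = []
    for k in range(1, n):
        diag_lines += _runs(np.diagonal(R, k))
        diag_lines += _runs(np.diagonal(R, -k))
    d_all = sum(diag_lines)
    d_long = [l for l in diag_lines if l >= l_min]
    det = sum(d_long) / d_all if d_all else 0.0
    mean_l = float(np.mean(d_long)) if d_long else 0.0
    l_max = max(diag_lines) if diag_lines else 0
    div = 1.0 / l_max if l_max else 0.0
    entr_l = _entropy(d_long)

    vert_lines: list[int] = []
    t1_gaps: list[int] = []
    t2_gaps: list[int] = []
    for j in range(n):
        col = R[:, j]
        vert_lines += _runs(col)
        pts = np.flatnonzero(col)
        if len(pts) >= 2:
            t1_gaps += list(np.diff(pts))
        starts = pts[np.flatnonzero(np.concatenate([[True], np.diff(pts) > 1]))] if len(pts) else pts
        if len(starts) >= 2:
            t2_gaps += list(np.diff(starts))
    v_all = sum(vert_lines)
    v_long = [v for v in vert_lines if v >= v_min]
    lam = sum(v_long) / v_all if v_all else 0.0
    tt = float(np.mean(v_long)) if v_long else 0.0
    v_max = max(vert_lines) if vert_lines else 0
    entr_v = _entropy(v_long)

    ratio = det / rr if rr else 0.0

    if n >= 3:
        ks = np.arange(1, n)
        rr_k = np.array([np.diagonal(R, k).mean() for k in ks])
        kc = ks - ks.mean()
        trend = float(np.dot(kc, rr_k - rr_k.mean()) / np.dot(kc, kc))
    else:
        trend = 0.0

    t1 = float(np.mean(t1_gaps)) if t1_gaps else 0.0
    t2 = float(np.mean(t2_gaps)) if t2_gaps else 0.0

    values = np.array([rr, det, mean_l, float(l_max), div, entr_l,
                       lam, tt, float(v_max), entr_v, ratio, trend, t1, t2])
    return FeatureBlock("rqa", list(RQA_VARIABLE_NAMES), values,
                        {"l_min": l_min, "v_min": v_min})


def rqa_features(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] | None = None,
    table: PropertyTable | None = None,
    m: int = 4,
    tau: int = 1,
    radius_frac: float = 0.20,
) -> FeatureBlock:
    """14 recurrence variables per property signal."""
    if table is None:
        table = load_property_table()
    props = tuple(table.names()) if properties is None else properties
    blocks = []
    for p in props:
        sig = encode_signal(seq, p, table, standardized=True)
        rm = recurrence_matrix(embed(sig, m, tau), radius_frac)
        b = rqa_variables(rm)
        blocks.append(FeatureBlock("rqa", [f"RQA[{p}]_{n}" for n in b.names], b.values))
    return concat_blocks(blocks, "rqa")


# --------------------------------------------------------------------------
# Discrete wavelet transform
# --------------------------------------------------------------------------

_STATS = ("max", "mean", "min", "sd")


def _coef_stats(c: np.ndarray | None) -> list[float]:
    if c is None or len(c) == 0:
        return [0.0, 0.0, 0.0, 0.0]
    return [float(c.max()), float(c.mean()), float(c.min()), float(c.std())]


def dwt_stats(
    signal,
    wavelet: str = "bior3.1",
    level: int = 5,
    prop: str | None = None,
) -> FeatureBlock:
    """Max/mean/min/sd of wavelet coefficients at each scale.

    4 x (level + 1) features: the approximation at the deepest scale first,
    then details at scales 1..level.  If the signal only supports a
    shallower decomposition the level is reduced (logged) and statistics of
    the absent detail scales are zero so the block length is invariant.
    """
    x = _values(signal)
    w = pywt.Wavelet(wavelet)
    if len(x) < w.dec_len:
        raise ValueError(f"signal length {len(x)} < filter length {w.dec_len}")
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    use_level = max(1, min(level, max_level))
    if use_level < level:
        logger.warning("signal length %d supports only %d decomposition levels (requested %d)",
                       len(x), use_level, level)
    coeffs = pywt.wavedec(x, w, level=use_level, mode="symmetric")
    approx = coeffs[0]
    details = {use_level - i: coeffs[i] for i in range(1, len(coeffs))}  # scale -> cD
    tag = f"[{prop}]" if prop else ""
    names = [f"DWT{tag}_A_{s}" for s in _STATS]
    values = _coef_stats(approx)
    for scale in range(1, level + 1):
        names += [f"DWT{tag}_D{scale}_{s}" for s in _STATS]
        values += _coef_stats(details.get(scale))
    return FeatureBlock("dwt", names, np.asarray(values),
                        {"wavelet": wavelet, "level": level})


def dwt_features(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] | None = None,
    table: PropertyTable | None = None,
    wavelet: str = "bior3.1",
    level: int = 5,
) -> FeatureBlock:
    if table is None:
        table = load_property_table()
    props = tuple(table.names()) if properties is None else properties
    return concat_blocks(
        [dwt_stats(encode_signal(seq, p, table), wavelet, level, prop=p) for p in props],
        "dwt",
    )


# --------------------------------------------------------------------------
# Empirical mode decomposition and Hilbert spectral entropy
# --------------------------------------------------------------------------

@dataclass
class ImfSet:
    """Intrinsic mode functions plus the final residual (sums to the input)."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for h in self.imfs:
            out = out + h
        return out


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (interior points)."""
    d = np.diff(x)
    maxima = np.flatnonzero((np.hstack([d, 0]) < 0) & (np.hstack([0, d]) > 0))
    minima = np.flatnonzero((np.hstack([d, 0]) > 0) & (np.hstack([0, d]) < 0))
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the given extrema, endpoints included
    as anchors (a simple boundary treatment adequate for short signals)."""
    n = len(x)
    knots = np.unique(np.concatenate([[0], idx, [n - 1]]))
    return CubicSpline(knots, x[knots])(np.arange(n))


def emd_sift(
    signal,
    max_imfs: int = 10,
    sd_threshold: float = 0.2,
    max_siftings: int = 10,
) -> ImfSet:
    """Empirical mode decomposition by envelope-mean sifting.

    Sifting of each mode stops when the Cauchy-type criterion
    SD = sum(m^2)/sum(h^2) falls below ``sd_threshold`` or after
    ``max_siftings`` passes; decomposition stops when the residual has
    fewer than 2 interior maxima + minima (monotone or constant tail) or
    ``max_imfs`` is reached.  A too-short or extrema-free input yields zero
    IMFs with the input as residual.
    """
    x = _values(signal).astype(float)
    if len(x) < 8:
        return ImfSet([], x.copy())
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _extrema(residual)
        if len(maxima) + len(minima) < 2:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _extrema(h)
            if len(mx) < 1 or len(mn) < 1:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = np.dot(h, h)
            if denom == 0 or np.dot(mean_env, mean_env) / denom < sd_threshold:
                h = h_new
                break
            h = h_new
        imfs.append(h)
        residual = residual - h
    return ImfSet(imfs, residual)


def imf_stats(imfs: ImfSet, n_keep: int = 6, prop: str | None = None) -> FeatureBlock:
    """Max/mean/min/sd for each of the first n_keep IMFs (zero-padded)."""
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    tag = f"[{prop}]" if prop else ""
    names, values = [], []
    for i in range(n_keep):
        c = imfs.imfs[i] if i < imfs.n_imfs else None
        names += [f"HHT{tag}_imf{i + 1}_{s}" for s in _STATS]
        values += _coef_stats(c)
    return FeatureBlock("hht", names, np.asarray(values), {"n_keep": n_keep})


def spectral_entropy(spectrum: np.ndarray) -> float:
    """Normalized Shannon entropy of a nonnegative spectrum.

    The spectrum is normalized to sum 1; the entropy is divided by
    log(number of components), so a single spectral line gives 0 and a flat
    spectrum gives 1.
    """
    p = np.asarray(spectrum, float)
    if p.ndim != 1 or len(p) < 2 or np.any(p < 0):
        raise ValueError("spectrum must be a nonnegative vector of length >= 2")
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def marginal_spectrum(imfs: ImfSet, n_bins: int = 64) -> np.ndarray:
    """Marginal Hilbert amplitude spectrum on n_bins over (0, 0.5] cycles/residue.

    Instantaneous frequency of each IMF from the unwrapped analytic phase;
    instantaneous amplitude accumulated into the frequency bins and summed
    over IMFs.
    """
    spec = np.zeros(n_bins)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    for h in imfs.imfs:
        z = _hilbert(h)
        amp = np.abs(z)
        phase = np.unwrap(np.angle(z))
        freq = np.abs(np.diff(phase)) / (2 * np.pi)
        freq = np.clip(freq, 0.0, 0.5)
        which = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, n_bins - 1)
        np.add.at(spec, which, 0.5 * (amp[:-1] + amp[1:]))
    return spec


def hhse(imfs: ImfSet, n_bins: int = 64) -> float:
    """Hilbert-Huang spectral entropy in [0, 1]."""
    if imfs.n_imfs < 1:
        raise ValueError("need at least one IMF")
    return spectral_entropy(marginal_spectrum(imfs, n_bins))


def hht_features(
    seq: SequenceRecord | str,
    properties: tuple[str, ...] | None = None,
    table: PropertyTable | None = None,
    n_keep: int = 6,
    n_bins: int = 64,
) -> FeatureBlock:
    """Per property: 4 x n_keep IMF statistics plus the spectral entropy.

    A signal producing no IMFs (monotone/constant) contributes zeros,
    including a 0 entropy slot, so the block length is invariant.
    """
    if table is None:
        table = load_property_table()
    props = tuple(table.names()) if properties is None else properties
    blocks = []
    for p in props:
        sig = encode_signal(seq, p, table, standardized=True)
        dec = emd_sift(sig)
        b = imf_stats(dec, n_keep, prop=p)
        ent = hhse(dec, n_bins) if dec.n_imfs else 0.0
        blocks.append(FeatureBlock(
            "hht", b.names + [f"HHT[{p}]_HHSE"], np.append(b.values, ent)))
    return concat_blocks(blocks, "hht")
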