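"""Independent reference implementations used as test oracles.

Each oracle is written against the defining procedure of its quantity with
deliberately different mechanics from the package implementation (pointer
copying instead of substring search, groupby run extraction instead of
manual scanning, rank statistics instead of curve integration), so that an
agreement between the two is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.stats import rankdata


def lz_complexity_oracle(s) -> int:
    """Lempel-Ziv 1976 complexity by character-wise pointer comparison
    (the Kaspar-Schuster scan, overlap-allowed copying)."""
    s = tuple(s)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    c, l, i, k, kmax = 1, 1, 0, 1, 1
    while l + k - 1 < n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            kmax = max(kmax, k)
            i += 1
            if i == l:
                c += 1
                l += kmax
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    if k > 1 or l < n:
        # the last component was entered but never closed by a mismatch
        c += 1
    return c


def _line_runs(values) -> list[int]:
    return [len(list(g)) for v, g in itertools.groupby(values) if v]


def _hist_entropy(lengths: list[int]) -> float:
    if not lengths:
        return 0.0
    counts = Counter(lengths)
    total = sum(counts.values())
    p = np.array([c / total for c in counts.values()])
    return float(-(p * np.log(p)).sum())


def rqa_oracle(R: np.ndarray, l_min: int = 2, v_min: int = 2) -> np.ndarray:
    """The 14 recurrence variables by direct enumeration (groupby runs).

    Same definitions as the package: diagonal statistics over every
    off-main diagonal, vertical statistics over full columns (main diagonal
    included), TREND by least-squares fit of diagonal density against the
    diagonal index, T1/T2 as mean vertical recurrence gaps.
    """
    R = np.asarray(R)
    n = R.shape[0]
    rr = R.sum() / n ** 2

    diag = []
    for k in range(1, n):
        diag += _line_runs(np.diagonal(R, k).tolist())
        diag += _line_runs(np.diagonal(R, -k).tolist())
    d_all = sum(diag)
    d_long = [x for x in diag if x >= l_min]
    det = sum(d_long) / d_all if d_all else 0.0
    mean_l = sum(d_long) / len(d_long) if d_long else 0.0
    l_max = max(diag) if diag else 0
    div = 1.0 / l_max if l_max else 0.0
    entr_l = _hist_entropy(d_long)

    vert, t1_gaps, t2_gaps = [], [], []
    for j in range(n):
        col = R[:, j].tolist()
        vert += _line_runs(col)
        pts = [i for i, v in enumerate(col) if v]
        for a, b in zip(pts, pts[1:]):
            t1_gaps.append(b - a)
        starts = [p for prev, p in zip([None] + pts, pts)
                  if prev is None or p - prev > 1]
        for a, b in zip(starts, starts[1:]):
            t2_gaps.append(b - a)
    v_all = sum(vert)
    v_long = [x for x in vert if x >= v_min]
    lam = sum(v_long) / v_all if v_all else 0.0
    tt = sum(v_long) / len(v_long) if v_long else 0.0
    v_max = max(vert) if vert else 0
    entr_v = _hist_entropy(v_long)

    ratio = det / rr if rr else 0.0
    if n >= 3:
        ks = np.arange(1, n)
        dens = np.array([np.diagonal(R, int(k)).mean() for k in ks])
        trend = float(np.polyfit(ks, dens, 1)[0])
    else:
        trend = 0.0
    t1 = sum(t1_gaps) / len(t1_gaps) if t1_gaps else 0.0
    t2 = sum(t2_gaps) / len(t2_gaps) if t2_gaps else 0.0
    return np.array([rr, det, mean_l, float(l_max), div, entr_l,
                     lam, tt, float(v_max), entr_v, ratio, trend, t1, t2])


def auc_mann_whitney(scores, truth) -> float:
    """AUC as the Mann-Whitney U statistic over n+ * n- (average ranks)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    ranks = rankdata(scores)
    n_pos = int((truth == 1).sum())
    n_neg = len(truth) - n_pos
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def mi_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) by explicit joint counting."""
    n = len(a)
    joint = Counter(zip(a.tolist(), b.tolist()))
    pa = Counter(a.tolist())
    pb = Counter(b.tolist())
    mi = 0.0
    for (x, z), c in joint.items():
        pxy = c / n
        mi += pxy * np.log(pxy / ((pa[x] / n) * (pb[z] / n)))
    return mi


def discretize_oracle(col: np.ndarray) -> np.ndarray:
    """mean +/- sd three-bin discretization of one feature column."""
    mu, sd = col.mean(), col.std()
    out = np.ones(len(col), dtype=int)
    out[col < mu - sd] = 0
    out[col > mu + sd] = 2
    return out
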