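"""mRMR ranking, incremental feature selection and two-step subset search.

For each binary class pair the pipeline first ranks features by maximum
relevance / minimum redundancy (mutual information on 3-bin discretized
features, Peng's mean +- sd scheme), then grows nested top-ranked subsets
in steps of 10, scoring each subset size and SVM parameter pair by
stratified 5-fold cross-validated accuracy.  The two-step procedure runs
this within each extraction method and then once more on the union of the
per-method winners, so the final subset is drawn from features that already
proved useful inside their own method.

Everything here is deterministic given the data, the configuration and the
fold seed; ties break toward the smaller subset, then the smaller C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: The paper-scale parameter grids (log2 C and log2 gamma).
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass
class RankedFeatures:
    """Feature indices in mRMR order with their greedy scores."""

    indices: list[int]
    scores: list[float]
    cap: int = 300

    def __post_init__(self) -> None:
        if len(self.indices) != len(set(self.indices)):
            raise ValueError("duplicate indices in ranking")
        if len(self.indices) > self.cap:
            raise ValueError("ranking longer than cap")


@dataclass
class SelectionResult:
    """Chosen subset, SVM parameters and the accuracy curve over sizes."""

    indices: list[int]
    C: float
    gamma: float
    cv_accuracy: float
    sizes: list[int] = field(default_factory=list)
    accuracy_curve: list[float] = field(default_factory=list)


def discretize(X: np.ndarray) -> np.ndarray:
    """3-bin discretization at mean +- sd per feature (Peng's convention)."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return ((X > mu - sd).astype(np.int8) + (X > mu + sd).astype(np.int8))


def _mi_columns(D: np.ndarray, v: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Mutual information (nats) of every column of D with vector v.

    Both D and v hold small nonnegative integer codes; vectorized joint
    counting over the bin product.
    """
    n, F = D.shape
    vb = int(v.max()) + 1
    mi = np.zeros(F)
    joint = np.zeros((n_bins, vb, F))
    for a in range(n_bins):
        Da = D == a
        for b in range(vb):
            joint[a, b] = (Da & (v == b)[:, None]).sum(axis=0)
    joint /= n
    pa = joint.sum(axis=1)  # n_bins x F
    pb = joint.sum(axis=0)  # vb x F
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pa[:, None, :] * pb[None, :, :])
        term = joint * np.log(ratio)
    mi = np.nansum(term, axis=(0, 1))
    return mi


def mrmr_rank(X: np.ndarray, y: np.ndarray, cap: int = 300, n_bins: int = 3) -> RankedFeatures:
    """Greedy mRMR ranking: argmax I(f; y) - mean_{s in S} I(f; s).

    Features are discretized with :func:`discretize`; the class vector is
    label-encoded.  Ties break toward the lower original index (argmax on
    ties returns the first maximum).  Requires both classes present with at
    least 2 samples each.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, yc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.min(np.bincount(yc)) < 2:
        raise ValueError("need at least 2 samples per class")
    D = discretize(X)
    F = X.shape[1]
    cap = min(cap, F)
    relevance = _mi_columns(D, yc.astype(np.int8), n_bins)
    chosen: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(F)
    available = np.ones(F, bool)
    for _ in range(cap):
        if chosen:
            score = relevance - redundancy_sum / len(chosen)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        best = int(np.argmax(score))
        chosen.append(best)
        scores.append(float(score[best]))
        available[best] = False
        redundancy_sum += _mi_columns(D, D[:, best], n_bins)
    return RankedFeatures(chosen, scores, cap=max(cap, len(chosen)))


def make_svm(C: float, gamma: float, class_weight: dict | None = None,
             probability: bool = False, seed: int = 0) -> SVC:
    """The RBF classifier used throughout (both selection and ensemble)."""
    # `probability` is only passed when requested: scikit-learn 1.9 warns on
    # any explicit value, including False, because the default is a sentinel.
    kwargs = {"probability": True} if probability else {}
    return SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight,
               random_state=seed, **kwargs)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                 class_weight: dict | None, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = make_svm(C, gamma, class_weight, seed=seed)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def ifs_search(
    ranked: RankedFeatures,
    X: np.ndarray,
    y: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] | None = None,
    gfo_gamma_fn=None,
    step: int = 10,
    folds: int = 5,
    class_weight: dict | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Incremental feature selection over nested top-ranked subsets.

    Subset sizes are step, 2*step, ... up to the ranking length (a ranking
    shorter than one step is evaluated whole).  At each size every (C,
    gamma) pair of the grid is scored by stratified k-fold CV accuracy;
    when ``gamma_grid`` is None the gamma is computed from the candidate
    feature matrix by ``gfo_gamma_fn`` (automatic kernel-width choice).
    The best (accuracy, then smallest size, then smallest C, then smallest
    gamma) wins.
    """
    if not ranked.indices:
        raise ValueError("empty ranking")
    X = np.asarray(X, float)
    y = np.asarray(y)
    sizes = list(range(step, len(ranked.indices) + 1, step))
    if not sizes:
        sizes = [len(ranked.indices)]
    best = None  # (acc, -, size, C, gamma, indices)
    curve = []
    for size in sizes:
        idx = ranked.indices[:size]
        Xs = X[:, idx]
        if gamma_grid is None:
            gammas = (gfo_gamma_fn(Xs),)
        else:
            gammas = gamma_grid
        size_best = 0.0
        for C in sorted(C_grid):
            for gamma in sorted(gammas):
                acc = _cv_accuracy(Xs, y, C, gamma, class_weight, folds, seed)
                size_best = max(size_best, acc)
                key = (acc, -size, -C, -gamma)
                if best is None or key > best[0]:
                    best = (key, SelectionResult(list(idx), C, gamma, acc))
        curve.append(size_best)
    result = best[1]
    result.sizes = sizes
    result.accuracy_curve = curve
    return result


def two_step_select(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    cap: int = 300,
    **ifs_kw,
) -> tuple[SelectionResult, dict[str, SelectionResult]]:
    """Two-step optimal feature selection over per-method feature blocks.

    Step 1 ranks and searches within each method's block; step 2 repeats
    the procedure on the union of the step-1 winners.  Returned indices are
    global positions in the concatenation of the blocks in dict order.
    """
    if not blocks:
        raise ValueError("need at least one method block")
    y = np.asarray(y)
    offsets: dict[str, int] = {}
    off = 0
    for name, Xb in blocks.items():
        offsets[name] = off
        off += Xb.shape[1]
    step1: dict[str, SelectionResult] = {}
    union: list[int] = []
    for name, Xb in blocks.items():
        ranked = mrmr_rank(Xb, y, cap=cap)
        res = ifs_search(ranked, Xb, y, **ifs_kw)
        res.indices = [offsets[name] + i for i in res.indices]
        step1[name] = res
        union.extend(res.indices)
    X_all = np.concatenate([np.asarray(Xb, float) for Xb in blocks.values()], axis=1)
    union = sorted(set(union))
    X_union = X_all[:, union]
    ranked2 = mrmr_rank(X_union, y, cap=cap)
    final = ifs_search(ranked2, X_union, y, **ifs_kw)
    final.indices = [union[i] for i in final.indices]
    return final, step1
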