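"""Two-stage one-against-one probabilistic SVM ensemble.

Stage 1 trains one binary RBF SVM with probability output per unordered
class pair, each on its own optimal feature subset found by the two-step
mRMR/IFS search; the k(k-1)/2 pairwise probabilities are coupled into a
k-dimensional class-probability vector (Wu-Lin-Weng second method, the
LIBSVM convention).  Stage 2 is a conventional one-against-one multiclass
RBF SVM over those probability vectors; it needs no feature selection.

The RBF width can be chosen automatically (GFO): gamma = 1/(2 sigma^2)
with sigma the mean Euclidean distance over all sample pairs.  Class
imbalance is handled by weighting every class by
largest-class-size / class-size at both stages.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .selection import (
    DEFAULT_C_GRID,
    SelectionResult,
    _cv_accuracy,
    ifs_search,
    make_svm,
    mrmr_rank,
    two_step_select,
)


def gfo_gamma(X: np.ndarray) -> float:
    """Automatic RBF kernel parameter: gamma = 1 / (2 sigma^2), sigma the
    mean Euclidean distance over all unordered sample pairs."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    sigma = pdist(X).mean()
    if sigma == 0:
        raise ValueError("all samples identical; GFO undefined")
    return 1.0 / (2.0 * sigma ** 2)


def class_weights(labels) -> dict[Any, float]:
    """largest class size divided by each class size (largest gets 1.0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    classes, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    return {c: top / n for c, n in zip(classes, counts)}


def train_binary_prob(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    weights: dict | None = None,
    seed: int = 0,
) -> SVC:
    """Fit one probabilistic binary RBF SVM (Platt-scaled outputs)."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("binary trainer needs exactly two classes")
    clf = make_svm(C, gamma, class_weight=weights, probability=True, seed=seed)
    with warnings.catch_warnings():
        # Platt-scaled SVC output is intrinsic to the method; silence the
        # scikit-learn 1.9 deprecation of `probability=True` at the fit site.
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        clf.fit(np.asarray(X, float), y)
    return clf


def couple_pairwise(pairwise: dict[tuple[int, int], float], k: int | None = None,
                    max_iter: int = 100) -> np.ndarray:
    """Couple pairwise probabilities into a class-probability vector.

    ``pairwise[(i, j)]`` (i < j) is the probability that class i beats
    class j.  Uses the Wu-Lin-Weng second method (the fixed-point iteration
    of LIBSVM's multiclass probability machinery); the output sums to 1 and
    reduces to [p, 1-p] for k = 2.
    """
    if k is None:
        k = max(max(p) for p in pairwise) + 1
    r = np.full((k, k), 0.5)
    for i, j in itertools.combinations(range(k), 2):
        if (i, j) not in pairwise:
            raise KeyError(f"missing pairwise probability for ({i}, {j})")
        pij = min(max(pairwise[(i, j)], 1e-7), 1 - 1e-7)
        r[i, j] = pij
        r[j, i] = 1 - pij
    if k == 2:
        return np.array([r[0, 1], r[1, 0]])
    Q = np.zeros((k, k))
    for t in range(k):
        Q[t, t] = sum(r[j, t] ** 2 for j in range(k) if j != t)
        for j in range(k):
            if j != t:
                Q[t, j] = -r[j, t] * r[t, j]
    p = np.full(k, 1.0 / k)
    eps = 0.005 / k
    for _ in range(max_iter):
        Qp = Q @ p
        pQp = float(p @ Qp)
        if np.max(np.abs(Qp - pQp)) < eps:
            break
        for t in range(k):
            diff = (-Qp[t] + pQp) / Q[t, t]
            p[t] += diff
            pQp = (pQp + diff * (diff * Q[t, t] + 2 * Qp[t])) / (1 + diff) ** 2
            Qp = (Qp + diff * Q[:, t]) / (1 + diff)
            p /= 1 + diff
    return p / p.sum()


@dataclass
class EnsembleConfig:
    """Everything that parameterizes selection and the two SVM stages."""

    cap: int = 300
    step: int = 10
    folds: int = 5
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] | None = None  # None -> GFO automatic gamma
    stage2_C_grid: tuple[float, ...] | None = None  # None -> same as C_grid
    seed: int = 0
    use_weights: bool = True


@dataclass
class PairModel:
    """One stage-1 member: feature subset, parameters, fitted classifier."""

    classes: tuple[Any, Any]
    indices: list[int]
    C: float
    gamma: float
    clf: SVC
    selection: SelectionResult | None = None


@dataclass
class TwoStageModel:
    """k(k-1)/2 stage-1 pair models plus the stage-2 multiclass SVM."""

    classes: list[Any]
    block_order: list[str]
    block_sizes: dict[str, int]
    pair_models: dict[tuple[int, int], PairModel]
    stage2: SVC
    stage2_params: tuple[float, float]
    config: EnsembleConfig

    def _concat(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        if list(blocks) != self.block_order:
            blocks = {name: blocks[name] for name in self.block_order}
        for name, size in self.block_sizes.items():
            if blocks[name].shape[1] != size:
                raise ValueError(
                    f"block {name!r}: expected {size} features, got {blocks[name].shape[1]}")
        return np.concatenate([np.asarray(blocks[n], float) for n in self.block_order], axis=1)

    def stage1_proba(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        """Coupled k-dimensional class-probability vectors (one row/sample)."""
        X = self._concat(blocks)
        k = len(self.classes)
        n = X.shape[0]
        pairwise_all: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), pm in self.pair_models.items():
            proba = pm.clf.predict_proba(X[:, pm.indices])
            col_i = list(pm.clf.classes_).index(self.classes[i])
            pairwise_all[(i, j)] = proba[:, col_i]
        out = np.empty((n, k))
        for s in range(n):
            out[s] = couple_pairwise({p: v[s] for p, v in pairwise_all.items()}, k)
        return out

    def predict(self, blocks: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Stage-2 labels plus the stage-1 probability vectors."""
        P = self.stage1_proba(blocks)
        return self.stage2.predict(P), P


def _pair_weights(y_pair: np.ndarray, use: bool) -> dict | None:
    return class_weights(y_pair) if use else None


def train_two_stage(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    config: EnsembleConfig | None = None,
) -> TwoStageModel:
    """Train the full two-stage ensemble.

    For every class pair: two-step mRMR/IFS selection on the pair's samples,
    then a probabilistic binary SVM on the chosen subset; every training
    sample is then re-expressed as its coupled probability vector and a
    multiclass SVM (parameters searched the same way, no selection) is fit
    on those vectors.
    """
    config = config or EnsembleConfig()
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < config.folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer than {config.folds} members; reduce folds")

    block_order = list(blocks)
    block_sizes = {n: blocks[n].shape[1] for n in block_order}
    X_all = np.concatenate([np.asarray(blocks[n], float) for n in block_order], axis=1)

    ifs_kw = dict(
        C_grid=config.C_grid,
        gamma_grid=config.gamma_grid,
        gfo_gamma_fn=gfo_gamma if config.gamma_grid is None else None,
        step=config.step,
        folds=config.folds,
        seed=config.seed,
    )

    pair_models: dict[tuple[int, int], PairModel] = {}
    for i, j in itertools.combinations(range(k), 2):
        mask = (y == classes[i]) | (y == classes[j])
        y_pair = y[mask]
        w = _pair_weights(y_pair, config.use_weights)
        pair_blocks = {n: np.asarray(blocks[n], float)[mask] for n in block_order}
        final, _ = two_step_select(pair_blocks, y_pair, cap=config.cap,
                                   class_weight=w, **ifs_kw)
        clf = train_binary_prob(X_all[mask][:, final.indices], y_pair,
                                final.C, final.gamma, weights=w, seed=config.seed)
        pair_models[(i, j)] = PairModel((classes[i], classes[j]), final.indices,
                                        final.C, final.gamma, clf, final)

    partial = TwoStageModel(classes, block_order, block_sizes, pair_models,
                            stage2=None, stage2_params=(0.0, 0.0), config=config)
    P = partial.stage1_proba(blocks)
    w_all = class_weights(y) if config.use_weights else None
    C2, g2 = _search_stage2(P, y, config, w_all)
    stage2 = make_svm(C2, g2, class_weight=w_all, seed=config.seed)
    stage2.fit(P, y)
    partial.stage2 = stage2
    partial.stage2_params = (C2, g2)
    return partial


def _search_stage2(P: np.ndarray, y: np.ndarray, config: EnsembleConfig,
                   weights: dict | None) -> tuple[float, float]:
    C_grid = config.stage2_C_grid or config.C_grid
    best = None
    if config.gamma_grid is None:
        gammas = (gfo_gamma(P),)
    else:
        gammas = config.gamma_grid
    for C in sorted(C_grid):
        for gamma in sorted(gammas):
            acc = _cv_accuracy(P, y, C, gamma, weights, config.folds, config.seed)
            key = (acc, -C, -gamma)
            if best is None or key > best[0]:
                best = (key, (C, gamma))
    return best[1]


@dataclass
class FrozenPairSpec:
    """A per-pair feature subset and parameters frozen from a previous fit
    (used by the final-system construction and the permutation analyses)."""

    indices: list[int]
    C: float
    gamma: float


def freeze(model: TwoStageModel) -> dict[tuple[int, int], FrozenPairSpec]:
    return {pair: FrozenPairSpec(pm.indices, pm.C, pm.gamma)
            for pair, pm in model.pair_models.items()}


def train_frozen(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    frozen: dict[tuple[int, int], FrozenPairSpec],
    config: EnsembleConfig,
    stage2_params: tuple[float, float] | None = None,
) -> TwoStageModel:
    """Retrain with frozen per-pair subsets and SVM parameters (no search).

    This is the trainer the randomization analyses use: features and
    hyperparameters stay fixed while the data (or its labels) change.
    """
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    k = len(classes)
    block_order = list(blocks)
    block_sizes = {n: blocks[n].shape[1] for n in block_order}
    X_all = np.concatenate([np.asarray(blocks[n], float) for n in block_order], axis=1)
    pair_models = {}
    for i, j in itertools.combinations(range(k), 2):
        spec = frozen[(i, j)]
        mask = (y == classes[i]) | (y == classes[j])
        y_pair = y[mask]
        w = _pair_weights(y_pair, config.use_weights)
        clf = train_binary_prob(X_all[mask][:, spec.indices], y_pair,
                                spec.C, spec.gamma, weights=w, seed=config.seed)
        pair_models[(i, j)] = PairModel((classes[i], classes[j]), spec.indices,
                                        spec.C, spec.gamma, clf)
    model = TwoStageModel(classes, block_order, block_sizes, pair_models,
                          stage2=None, stage2_params=(0.0, 0.0), config=config)
    P = model.stage1_proba(blocks)
    w_all = class_weights(y) if config.use_weights else None
    if stage2_params is None:
        C2, g2 = _search_stage2(P, y, config, w_all)
    else:
        C2, g2 = stage2_params
    stage2 = make_svm(C2, g2, class_weight=w_all, seed=config.seed)
    stage2.fit(P, y)
    model.stage2 = stage2
    model.stage2_params = (C2, g2)
    return model


def finalize(
    turn_models: list[TwoStageModel],
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    config: EnsembleConfig,
) -> TwoStageModel:
    """Build the final prediction system from leave-one-out turn models.

    Per pair, the feature subset is the union of every turn's optimal
    subset and (C, gamma) are the averages of the per-turn optima, averaged
    in log2 space; the system is then retrained on the full dataset with
    those frozen choices.
    """
    if not turn_models:
        raise ValueError("no turn models")
    pairs = turn_models[0].pair_models.keys()
    frozen = {}
    for pair in pairs:
        idx = sorted(set().union(*(m.pair_models[pair].indices for m in turn_models)))
        C = 2 ** np.mean([np.log2(m.pair_models[pair].C) for m in turn_models])
        g = 2 ** np.mean([np.log2(m.pair_models[pair].gamma) for m in turn_models])
        frozen[pair] = FrozenPairSpec(idx, float(C), float(g))
    return train_frozen(blocks, y, frozen, config)
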