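"""Evaluation: one-vs-rest metrics, ROC/AUC, jackknife and k-fold
harnesses, the multi-localization criterion, and the two randomization
analyses that probe whether the optimal feature subsets carry real class
information.

"Sp" magnitudes reported for this problem in the literature are consistent
with either specificity or precision under class imbalance, so both are
computed and clearly named (``Sp`` = TN/(TN+FP) specificity proper,
``precision`` = TP/(TP+FP)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .ensemble import (
    EnsembleConfig,
    FrozenPairSpec,
    TwoStageModel,
    class_weights,
    gfo_gamma,
    train_two_stage,
)
from .selection import make_svm


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    classes: list[Any]
    tp: dict[Any, int]
    tn: dict[Any, int]
    fp: dict[Any, int]
    fn: dict[Any, int]
    total: int


@dataclass
class EvaluationReport:
    overall_accuracy: float
    sensitivity: dict[Any, float]
    specificity: dict[Any, float]
    precision: dict[Any, float]
    mcc: dict[Any, float]
    counts: ConfusionCounts | None = None
    aucs: dict[Any, float] = field(default_factory=dict)


def confusion(true: Sequence, pred: Sequence, classes: Sequence) -> ConfusionCounts:
    """One-vs-rest confusion counts for each class."""
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ValueError("label lists differ in length")
    cset = set(classes)
    stray = [x for x in itertools.chain(true, pred) if x not in cset]
    if stray:
        raise ValueError(f"labels outside class list: {sorted(set(map(str, stray)))}")
    tp, tn, fp, fn = {}, {}, {}, {}
    for c in classes:
        tp[c] = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fn[c] = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        fp[c] = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        tn[c] = sum(1 for t, p in zip(true, pred) if t != c and p != c)
    return ConfusionCounts(list(classes), tp, tn, fp, fn, len(true))


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """OA, per-class sensitivity, specificity, precision and MCC.

    A zero factor in the MCC denominator (or an empty positive/negative
    margin for Sn/Sp) yields 0 by convention.
    """
    sn, sp, prec, mcc = {}, {}, {}, {}
    for c in counts.classes:
        TP, TN, FP, FN = counts.tp[c], counts.tn[c], counts.fp[c], counts.fn[c]
        sn[c] = TP / (TP + FN) if TP + FN else 0.0
        sp[c] = TN / (TN + FP) if TN + FP else 0.0
        prec[c] = TP / (TP + FP) if TP + FP else 0.0
        denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
        mcc[c] = (TP * TN - FP * FN) / np.sqrt(denom) if denom else 0.0
    oa = sum(counts.tp.values()) / counts.total if counts.total else 0.0
    return EvaluationReport(oa, sn, sp, prec, mcc, counts)


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and trapezoidal AUC.

    ``truth`` is 0/1 with the positive class coded 1; both classes must be
    present.  Ties in scores step diagonally (simultaneous threshold move).
    """
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present in truth")
    fpr, tpr, _ = _sk_roc_curve(truth, np.asarray(scores, float))
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def multiloc_accuracy(true_sets: Sequence[set], pred: Sequence) -> float:
    """Any-match criterion: a prediction is correct if it is one of the
    protein's annotated localizations."""
    true_sets = [set(s) for s in true_sets]
    if any(not s for s in true_sets):
        raise ValueError("empty true label set")
    if len(true_sets) != len(pred):
        raise ValueError("length mismatch")
    return sum(1 for s, p in zip(true_sets, pred) if p in s) / len(pred)


# --------------------------------------------------------------------------
# Cross-validation harnesses
# --------------------------------------------------------------------------

Trainer = Callable[[dict[str, np.ndarray], np.ndarray], TwoStageModel]


def _slice_blocks(blocks: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {n: np.asarray(X, float)[idx] for n, X in blocks.items()}


def jackknife(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    trainer: Trainer,
    collect_models: bool = False,
) -> tuple[EvaluationReport, np.ndarray, list[TwoStageModel]]:
    """Leave-one-out evaluation: each sample held out in turn, the trainer
    (including any feature ranking/selection it performs) refit on the rest.
    Aggregated predictions are scored once."""
    y = np.asarray(y)
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    models: list[TwoStageModel] = []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        model = trainer(_slice_blocks(blocks, tr), y[tr])
        lab, _ = model.predict(_slice_blocks(blocks, np.array([i])))
        preds[i] = lab[0]
        if collect_models:
            models.append(model)
    classes = sorted(np.unique(y).tolist())
    return metrics(confusion(y, preds, classes)), preds, models


def kfold_eval(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    trainer: Trainer,
    folds: int = 5,
    seed: int = 0,
) -> tuple[EvaluationReport, np.ndarray]:
    """Stratified k-fold analogue of the jackknife harness."""
    y = np.asarray(y)
    preds = np.empty(len(y), dtype=y.dtype)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    first = next(iter(blocks.values()))
    for tr, te in skf.split(np.asarray(first), y):
        model = trainer(_slice_blocks(blocks, tr), y[tr])
        lab, _ = model.predict(_slice_blocks(blocks, te))
        preds[te] = lab
    classes = sorted(np.unique(y).tolist())
    return metrics(confusion(y, preds, classes)), preds


# --------------------------------------------------------------------------
# Randomization analyses
# --------------------------------------------------------------------------

def _binary_cv_error(X: np.ndarray, y: np.ndarray, C: float, gamma: float | None,
                     folds: int, seed: int, use_weights: bool = True) -> float:
    """Stratified k-fold misclassification rate of one binary RBF SVM with
    frozen parameters (gamma None -> GFO on the training fold)."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = 0
    for tr, te in skf.split(X, y):
        w = class_weights(y[tr]) if use_weights else None
        if gamma is None:
            try:
                g = gfo_gamma(X[tr])
            except ValueError:
                # all training rows identical (e.g. a random draw of constant
                # features): nothing is learnable, vote the majority class
                classes, counts = np.unique(y[tr], return_counts=True)
                wrong += int((y[te] != classes[counts.argmax()]).sum())
                continue
        else:
            g = gamma
        clf = make_svm(C, g, class_weight=w, seed=seed)
        clf.fit(X[tr], y[tr])
        wrong += int((clf.predict(X[te]) != y[te]).sum())
    return wrong / len(y)


@dataclass
class RandomizationResult:
    original_error: float
    mean_error: dict[Any, float]
    sd_error: dict[Any, float]
    rounds: int


def permutation_label_test(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float | None,
    rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> RandomizationResult:
    """Label-permutation analysis with frozen SVM hyperparameters.

    Class memberships are shuffled ``rounds`` times while features stay
    fixed; each shuffled dataset is re-evaluated with the same CV protocol
    and the same (C, gamma) that were optimal on the original data.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    original = _binary_cv_error(X, y, C, gamma, folds, seed)
    errs = []
    for _ in range(rounds):
        errs.append(_binary_cv_error(X, rng.permutation(y), C, gamma, folds, seed))
    errs = np.asarray(errs)
    return RandomizationResult(original, {"permuted": float(errs.mean())},
                               {"permuted": float(errs.std())}, rounds)


def random_feature_test(
    X_pool: np.ndarray,
    y: np.ndarray,
    optimal: Sequence[int],
    C: float,
    gamma: float | None,
    fractions: tuple[float, ...] = (0.25, 0.5, 1.0),
    rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> RandomizationResult:
    """Random-feature-subset analysis with frozen SVM hyperparameters.

    For each fraction of the optimal subset size, K features are drawn at
    random from the pool ``rounds`` times and evaluated with the same CV
    protocol; compared against the error of the optimal subset itself.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    optimal = list(optimal)
    pool_size = X_pool.shape[1]
    original = _binary_cv_error(X_pool[:, optimal], y, C, gamma, folds, seed)
    mean_e, sd_e = {}, {}
    for frac in fractions:
        K = max(1, round(frac * len(optimal)))
        if K > pool_size:
            raise ValueError(f"K={K} exceeds pool size {pool_size}")
        errs = []
        for _ in range(rounds):
            sub = rng.choice(pool_size, size=K, replace=False)
            errs.append(_binary_cv_error(X_pool[:, sub], y, C, gamma, folds, seed))
        errs = np.asarray(errs)
        mean_e[frac] = float(errs.mean())
        sd_e[frac] = float(errs.std())
    return RandomizationResult(original, mean_e, sd_e, rounds)


def permutation_label_test_multiclass(
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    frozen: dict[tuple[int, int], FrozenPairSpec],
    config: EnsembleConfig,
    stage2_params: tuple[float, float],
    rounds: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> RandomizationResult:
    """Whole-system label permutation: the two-stage ensemble is retrained
    with frozen per-pair subsets/parameters on shuffled labels and scored
    by stratified k-fold CV."""
    from .ensemble import train_frozen

    rng = np.random.default_rng(seed)
    y = np.asarray(y)

    def cv_error(yy: np.ndarray) -> float:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        first = next(iter(blocks.values()))
        wrong = 0
        for tr, te in skf.split(np.asarray(first), yy):
            model = train_frozen(_slice_blocks(blocks, tr), yy[tr], frozen,
                                 config, stage2_params)
            lab, _ = model.predict(_slice_blocks(blocks, te))
            wrong += int((lab != yy[te]).sum())
        return wrong / len(yy)

    original = cv_error(y)
    errs = np.array([cv_error(rng.permutation(y)) for _ in range(rounds)])
    return RandomizationResult(original, {"permuted": float(errs.mean())},
                               {"permuted": float(errs.std())}, rounds)
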