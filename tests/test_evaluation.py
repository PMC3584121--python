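import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_mann_whitney
from subnucpred.ensemble import EnsembleConfig, train_two_stage
from subnucpred.evaluation import (
    confusion,
    jackknife,
    kfold_eval,
    metrics,
    multiloc_accuracy,
    permutation_label_test,
    random_feature_test,
    roc_auc,
)

SMALL_CONF = EnsembleConfig(cap=4, step=2, C_grid=(1.0, 8.0), seed=0)


class TestConfusionMetrics:
    def test_hand_example(self):
        true = ["a", "a", "a", "b", "b", "c"]
        pred = ["a", "a", "b", "b", "b", "a"]
        rep = metrics(confusion(true, pred, ["a", "b", "c"]))
        assert np.isclose(rep.overall_accuracy, 4 / 6)
        assert np.isclose(rep.sensitivity["a"], 2 / 3)
        assert np.isclose(rep.specificity["a"], 2 / 3)
        assert np.isclose(rep.precision["b"], 2 / 3)
        assert rep.sensitivity["c"] == 0.0
        assert rep.mcc["c"] <= 0.0

    def test_stray_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["z"], ["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a", "b"], ["a"], ["a", "b"])

    def test_mcc_sign_flips_on_inversion(self):
        true = ["a"] * 6 + ["b"] * 4
        pred = ["a", "a", "a", "a", "b", "b", "b", "b", "a", "b"]
        inv = ["b" if p == "a" else "a" for p in pred]
        m1 = metrics(confusion(true, pred, ["a", "b"])).mcc["a"]
        m2 = metrics(confusion(true, inv, ["a", "b"])).mcc["a"]
        assert np.isclose(m1, -m2)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10 ** 6))
    def test_metric_bounds(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["a", "b", "c"]
        true = rng.choice(classes, 30).tolist()
        pred = rng.choice(classes, 30).tolist()
        rep = metrics(confusion(true, pred, classes))
        assert 0.0 <= rep.overall_accuracy <= 1.0
        for c in classes:
            assert 0.0 <= rep.sensitivity[c] <= 1.0
            assert 0.0 <= rep.specificity[c] <= 1.0
            assert -1.0 <= rep.mcc[c] <= 1.0


class TestROC:
    def test_perfect_separation(self):
        _, _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_mann_whitney_equivalence_sample(self):
        # 200-set sweep lives in the acceptance suite
        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = np.array([0] * 10 + [1] * 10)
            scores = np.round(rng.normal(size=20), 1)
            _, _, auc = roc_auc(scores, truth)
            assert np.isclose(auc, auc_mann_whitney(scores, truth))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestMultiLoc:
    def test_stated_criterion(self):
        assert multiloc_accuracy([{"A", "B"}], ["A"]) == 1.0

    def test_miss(self):
        assert multiloc_accuracy([{"A"}], ["B"]) == 0.0

    def test_all_hits(self):
        assert multiloc_accuracy([{"A"}, {"B", "C"}], ["A", "C"]) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            multiloc_accuracy([set()], ["A"])


def _binary_blocks(seed=0, n=20):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c * 2, 0.5, size=(n, 4)) for c in range(2)])
    y = np.repeat(["a", "b"], n)
    return {"m": X}, y


class TestHarnesses:
    def test_jackknife_no_leakage(self):
        """The held-out sample must never reach the trainer."""
        blocks, y = _binary_blocks()
        n = len(y)
        seen_sizes = []
        held_out_rows = []

        def trainer(b, yy):
            seen_sizes.append(len(yy))
            held_out_rows.append(b["m"])
            return train_two_stage(b, yy, SMALL_CONF)

        report, preds, _ = jackknife(blocks, y, trainer)
        assert seen_sizes == [n - 1] * n
        for i, Xtr in enumerate(held_out_rows):
            # the row held out on turn i is absent from that turn's matrix
            assert not np.any(np.all(Xtr == blocks["m"][i], axis=1))
        assert preds.shape == (n,)
        assert report.overall_accuracy >= 0.9  # well-separated classes

    def test_kfold_covers_every_sample(self):
        blocks, y = _binary_blocks()
        report, preds = kfold_eval(blocks, y, lambda b, yy: train_two_stage(b, yy, SMALL_CONF))
        assert preds.shape == y.shape
        assert set(np.unique(preds)) <= {"a", "b"}


class TestRandomization:
    def test_permutation_rounds_recorded(self):
        blocks, y = _binary_blocks()
        X = blocks["m"]
        res = permutation_label_test(X, y, C=8.0, gamma=0.5, rounds=50, seed=0)
        assert res.rounds == 50
        # separable originals beat shuffled labels by a wide margin
        assert res.original_error < res.mean_error["permuted"] - 2 * res.sd_error["permuted"]

    def test_permuted_error_near_null(self):
        blocks, y = _binary_blocks()
        res = permutation_label_test(blocks["m"], y, C=8.0, gamma=0.5, rounds=30, seed=1)
        # balanced binary null: error about 1 - max class frequency = 0.5
        assert abs(res.mean_error["permuted"] - 0.5) < 0.15

    def test_random_subset_degenerate_control(self):
        # pool restricted to the optimal subset itself, fraction 1.0:
        # every draw is a permutation of the same features -> identical error
        blocks, y = _binary_blocks()
        X = blocks["m"]
        optimal = [0, 1, 2, 3]
        res = random_feature_test(X, y, optimal, C=8.0, gamma=0.5,
                                  fractions=(1.0,), rounds=5, seed=0)
        assert res.sd_error[1.0] == 0.0
        assert res.mean_error[1.0] == res.original_error

    def test_k_exceeding_pool_rejected(self):
        blocks, y = _binary_blocks()
        with pytest.raises(ValueError):
            random_feature_test(blocks["m"][:, :2], y, [0, 1], C=1.0,
                                gamma=0.5, fractions=(2.0,), rounds=2, seed=0)
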