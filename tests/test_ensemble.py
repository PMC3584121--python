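import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subnucpred.ensemble import (
    EnsembleConfig,
    class_weights,
    couple_pairwise,
    finalize,
    freeze,
    gfo_gamma,
    train_frozen,
    train_two_stage,
)

SMALL_CONF = EnsembleConfig(cap=6, step=3, C_grid=(1.0, 8.0), seed=0)


def _three_class_blocks(seed=0, n=15, spread=0.4):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, spread, size=(n, 5)) for c in range(3)])
    noise = rng.normal(size=(3 * n, 4))
    y = np.repeat(["a", "b", "c"], n)
    return {"sig": X, "noise": noise}, y


class TestGFO:
    def test_two_points(self):
        # distance 2 -> sigma 2 -> gamma 1/8
        assert gfo_gamma(np.array([[0.0, 0.0], [2.0, 0.0]])) == 0.125

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            gfo_gamma(np.zeros((4, 3)))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            gfo_gamma(np.zeros((1, 3)))


class TestClassWeights:
    def test_unbalanced_contract(self):
        w = class_weights(["A"] * 100 + ["B"] * 20)
        assert w["A"] == 1.0
        assert w["B"] == 5.0

    def test_balanced_all_ones(self):
        w = class_weights(["A", "B", "A", "B"])
        assert w == {"A": 1.0, "B": 1.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])


class TestCoupling:
    def test_two_class_reduction(self):
        assert np.allclose(couple_pairwise({(0, 1): 0.7}), [0.7, 0.3])

    def test_uniform_three_class(self):
        p = couple_pairwise({(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        assert np.allclose(p, 1 / 3)

    def test_dominant_class_wins(self):
        p = couple_pairwise({(0, 1): 0.9, (0, 2): 0.9, (1, 2): 0.5})
        assert np.argmax(p) == 0

    def test_missing_pair_rejected(self):
        with pytest.raises(KeyError):
            couple_pairwise({(0, 1): 0.5, (0, 2): 0.5}, k=3)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(2, 5), st.integers(0, 10 ** 6))
    def test_output_on_simplex(self, k, seed):
        rng = np.random.default_rng(seed)
        pairwise = {(i, j): float(rng.uniform(0.01, 0.99))
                    for i in range(k) for j in range(i + 1, k)}
        p = couple_pairwise(pairwise, k)
        assert np.isclose(p.sum(), 1.0)
        assert np.all(p >= 0)


class TestTwoStage:
    def test_train_predict_shapes(self):
        blocks, y = _three_class_blocks()
        model = train_two_stage(blocks, y, SMALL_CONF)
        labels, proba = model.predict(blocks)
        assert labels.shape == (45,)
        assert proba.shape == (45, 3)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert len(model.pair_models) == 3

    def test_separable_data_learned(self):
        blocks, y = _three_class_blocks()
        model = train_two_stage(blocks, y, SMALL_CONF)
        labels, _ = model.predict(blocks)
        assert (labels == y).mean() >= 0.95

    def test_deterministic_given_seed(self):
        blocks, y = _three_class_blocks()
        m1 = train_two_stage(blocks, y, SMALL_CONF)
        m2 = train_two_stage(blocks, y, SMALL_CONF)
        assert np.array_equal(m1.predict(blocks)[1], m2.predict(blocks)[1])
        for pair in m1.pair_models:
            assert m1.pair_models[pair].indices == m2.pair_models[pair].indices
            assert m1.pair_models[pair].C == m2.pair_models[pair].C

    def test_block_size_mismatch_rejected(self):
        blocks, y = _three_class_blocks()
        model = train_two_stage(blocks, y, SMALL_CONF)
        bad = {"sig": blocks["sig"][:, :3], "noise": blocks["noise"]}
        with pytest.raises(ValueError):
            model.predict(bad)

    def test_single_class_rejected(self):
        blocks, _ = _three_class_blocks()
        with pytest.raises(ValueError):
            train_two_stage(blocks, np.repeat(["a"], 45), SMALL_CONF)

    def test_tiny_class_rejected(self):
        blocks, y = _three_class_blocks()
        y = y.copy()
        y[y == "c"] = "a"
        y[-2:] = "c"  # only 2 members < 5 folds
        with pytest.raises(ValueError):
            train_two_stage(blocks, y, SMALL_CONF)


class TestFrozenAndFinalize:
    def test_freeze_roundtrip(self):
        blocks, y = _three_class_blocks()
        model = train_two_stage(blocks, y, SMALL_CONF)
        frozen = freeze(model)
        re = train_frozen(blocks, y, frozen, SMALL_CONF, model.stage2_params)
        assert np.array_equal(re.predict(blocks)[0], model.predict(blocks)[0])

    def test_finalize_unions_subsets(self):
        blocks, y = _three_class_blocks()
        m1 = train_two_stage(blocks, y, SMALL_CONF)
        m2 = train_two_stage(blocks, y, EnsembleConfig(cap=6, step=3,
                                                       C_grid=(1.0, 8.0), seed=1))
        final = finalize([m1, m2], blocks, y, SMALL_CONF)
        for pair, pm in final.pair_models.items():
            want = set(m1.pair_models[pair].indices) | set(m2.pair_models[pair].indices)
            assert set(pm.indices) == want
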