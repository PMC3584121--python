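import numpy as np
import pytest

from oracles import rqa_oracle
from subnucpred.signal_features import (
    RQA_VARIABLE_NAMES,
    ImfSet,
    dwt_features,
    dwt_stats,
    embed,
    emd_sift,
    hhse,
    marginal_spectrum,
    recurrence_matrix,
    rqa_features,
    rqa_variables,
    spectral_entropy,
)


class TestEmbedding:
    def test_shape_and_content(self):
        pts = embed(np.arange(5.0), m=4, tau=1)
        assert pts.shape == (2, 4)
        assert np.array_equal(pts[0], [0, 1, 2, 3])
        assert np.array_equal(pts[1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed(np.arange(3.0), m=4, tau=1)


class TestRecurrenceMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        rm = recurrence_matrix(rng.normal(size=(12, 4)))
        assert np.array_equal(rm.matrix, rm.matrix.T)
        assert np.all(np.diag(rm.matrix) == 1)

    def test_coincident_points_all_ones(self):
        rm = recurrence_matrix(np.zeros((5, 3)))
        assert np.all(rm.matrix == 1)

    def test_threshold_is_fraction_of_mean_distance(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        rm = recurrence_matrix(pts, radius_frac=0.5)
        # mean pair distance = (1+2+1)/3, threshold = 2/3
        assert np.isclose(rm.threshold, 0.5 * 4 / 3)


class TestRQAVariables:
    def test_fourteen_named_variables(self):
        b = rqa_variables(np.eye(4, dtype=np.int8))
        assert tuple(b.names) == RQA_VARIABLE_NAMES
        assert len(b.values) == 14

    def test_all_ones_matrix(self):
        b = rqa_variables(np.ones((6, 6), dtype=np.int8))
        d = dict(zip(b.names, b.values))
        assert d["RR"] == 1.0
        assert d["LAM"] == 1.0  # verticals include the main diagonal
        assert d["TT"] == 6.0
        assert d["Vmax"] == 6.0

    def test_identity_matrix(self):
        b = rqa_variables(np.eye(5, dtype=np.int8))
        d = dict(zip(b.names, b.values))
        assert d["RR"] == 0.2
        assert d["DET"] == 0.0  # no off-diagonal lines at all
        assert d["LAM"] == 0.0  # columns hold single points only

    def test_oracle_agreement_random_matrices(self):
        # the exhaustive 4x4 sweep lives in the acceptance suite
        rng = np.random.default_rng(1)
        for n in (4, 5, 6, 8):
            for _ in range(40):
                R = (rng.random((n, n)) < 0.4).astype(np.int8)
                assert np.allclose(rqa_variables(R).values, rqa_oracle(R))

    def test_per_property_block(self, table):
        b = rqa_features("ACDEFGHIKLMNPQRSTVWY" * 3, table=table)
        assert len(b.values) == 14 * 29


class TestDWT:
    def test_dimension_and_names(self, table):
        sig = np.sin(np.arange(120) / 3.0)
        b = dwt_stats(sig, prop="P")
        assert len(b.values) == 24  # (A5 + D1..D5) x 4 statistics

    def test_constant_signal_details_vanish(self):
        b = dwt_stats(np.full(100, 2.0))
        d = dict(zip(b.names, b.values))
        sds = [v for n, v in d.items() if "_sd" in n and "_A" not in n]
        assert np.allclose(sds, 0.0, atol=1e-10)

    def test_short_signal_levels_zero_padded(self):
        # too short for 5 levels: missing scales present but all-zero
        b = dwt_stats(np.sin(np.arange(12.0)))
        assert len(b.values) == 24

    def test_below_filter_length_rejected(self):
        with pytest.raises(ValueError):
            dwt_stats(np.arange(3.0))

    def test_per_property_block(self, table):
        b = dwt_features("ACDEFGHIKLMNPQRSTVWY" * 3, table=table)
        assert len(b.values) == 24 * 29


class TestEMD:
    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(0)
        x = np.sin(np.arange(200) / 5.0) + 0.3 * rng.normal(size=200)
        dec = emd_sift(x)
        assert dec.n_imfs >= 1
        err = np.abs(dec.reconstruct() - x).max() / np.abs(x).max()
        assert err < 1e-8

    def test_monotone_signal_yields_no_imfs(self):
        dec = emd_sift(np.arange(50.0))
        assert dec.n_imfs == 0
        assert np.array_equal(dec.residual, np.arange(50.0))

    def test_too_short_signal_yields_no_imfs(self):
        dec = emd_sift(np.array([1.0, -1.0, 1.0]))
        assert dec.n_imfs == 0

    def test_pure_tone_first_imf_correlates(self):
        x = np.sin(2 * np.pi * np.arange(256) / 16.0)
        dec = emd_sift(x)
        r = np.corrcoef(dec.imfs[0], x)[0, 1]
        assert r > 0.99


class TestSpectralEntropy:
    def test_single_line_is_zero(self):
        spec = np.zeros(64)
        spec[10] = 3.0
        assert spectral_entropy(spec) == 0.0

    def test_uniform_is_one(self):
        assert np.isclose(spectral_entropy(np.ones(64)), 1.0)

    def test_empty_spectrum_is_zero(self):
        assert spectral_entropy(np.zeros(64)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.array([1.0, -1.0]))

    def test_hhse_bounds_and_ordering(self):
        rng = np.random.default_rng(0)
        tone = emd_sift(np.sin(2 * np.pi * np.arange(256) / 16.0))
        noise = emd_sift(rng.normal(size=256))
        h_tone, h_noise = hhse(tone), hhse(noise)
        assert 0.0 <= h_tone <= 1.0 and 0.0 <= h_noise <= 1.0
        assert h_tone < h_noise  # a pure tone concentrates the spectrum

    def test_hhse_requires_imfs(self):
        with pytest.raises(ValueError):
            hhse(ImfSet([], np.arange(10.0)))

    def test_marginal_spectrum_shape(self):
        dec = emd_sift(np.sin(np.arange(100) / 4.0))
        spec = marginal_spectrum(dec)
        assert spec.shape == (64,)
        assert np.all(spec >= 0)
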