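import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import lz_complexity_oracle
from subnucpred.alphabets import get_scheme, list_schemes
from subnucpred.comp_features import (
    gd_all,
    global_descriptor,
    laac,
    laac_all,
    ldc,
    ldc_all,
    lz_complexity,
    lzc_features,
)


class TestLZComplexity:
    def test_classic_worked_example(self):
        # the canonical LZ76 example sequence decomposes into 6 components
        assert lz_complexity("0001101001000101") == 6

    def test_single_symbol(self):
        assert lz_complexity("A") == 1

    def test_homopolymer(self):
        assert lz_complexity("AAAA") == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lz_complexity("")

    def test_oracle_agreement_small_strings(self):
        # the exhaustive sweep up to length 10 lives in the acceptance suite
        for a in (1, 2, 3):
            alph = "ABC"[:a]
            for L in range(1, 7):
                for t in itertools.product(alph, repeat=L):
                    s = "".join(t)
                    assert lz_complexity(s) == lz_complexity_oracle(s), s

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=40))
    def test_relabeling_invariance(self, symbols):
        # complexity depends on the copy structure, not the symbol identities
        relabeled = tuple(2 - s for s in symbols)
        assert lz_complexity(tuple(symbols)) == lz_complexity(relabeled)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=40))
    def test_bounds(self, symbols):
        c = lz_complexity(tuple(symbols))
        assert 1 <= c <= len(symbols)


class TestLAAC:
    def test_dimension_and_window_sums(self):
        sch = get_scheme("7-Cat")
        b = laac("ACDEFGHIKLMNPQRSTVWY" * 6, sch)
        assert len(b.values) == 2 * sch.k
        assert np.isclose(b.values[: sch.k].sum(), 1.0)
        assert np.isclose(b.values[sch.k:].sum(), 1.0)

    def test_short_sequence_truncates_window(self):
        sch = get_scheme("HP")
        b = laac("ACDEF", sch)  # shorter than both windows
        assert np.isclose(b.values[: sch.k].sum(), 1.0)

    def test_all_schemes_total(self):
        b = laac_all("ACDEFGHIKLMNPQRSTVWY" * 6)
        expected = sum(2 * s.k for s in list_schemes("all"))
        assert len(b.values) == expected
        assert len(set(b.names)) == expected


class TestLDC:
    def test_dimension(self):
        sch = get_scheme("HP")
        b = ldc("ACDEFGHIKLMNPQRSTVWY" * 6, sch)
        assert len(b.values) == 2 * sch.k ** 2

    def test_window_normalization(self):
        sch = get_scheme("HP")
        b = ldc("ACDEFGHIKLMNPQRSTVWY" * 6, sch)
        k2 = sch.k ** 2
        assert np.isclose(b.values[:k2].sum(), 1.0)
        assert np.isclose(b.values[k2:].sum(), 1.0)

    def test_single_residue_gives_zero_blocks(self):
        sch = get_scheme("HP")
        b = ldc("A", sch)
        assert np.all(b.values == 0)

    def test_default_subset(self):
        b = ldc_all("ACDEFGHIKLMNPQRSTVWY" * 6)
        ks = [s.k for s in list_schemes(["HP", "DHP", "7-Cat", "ms", "lesk", "Murphy8"])]
        assert len(b.values) == sum(2 * k * k for k in ks)


class TestGlobalDescriptor:
    def test_dimension(self):
        for name in ("HP", "7-Cat", "Murphy8"):
            sch = get_scheme(name)
            b = global_descriptor("ACDEFGHIKLMNPQRSTVWY" * 3, sch)
            k = sch.k
            assert len(b.values) == k + k * (k - 1) // 2 + 5 * k

    def test_composition_sums_to_one(self):
        sch = get_scheme("HP")
        b = global_descriptor("ACDEFGHIKLMNPQRSTVWY", sch)
        assert np.isclose(b.values[: sch.k].sum(), 1.0)

    def test_transition_worked_example(self):
        # HP symbols of "AD" are (1, 2): one unequal adjacency over 1 slot
        sch = get_scheme("HP")
        b = global_descriptor("AD", sch)
        tran = b.values[sch.k]
        assert tran == 1.0

    def test_distribution_positions(self):
        # "AAAD" under HP: group 1 at 1..3, group 2 at position 4
        sch = get_scheme("HP")
        b = global_descriptor("AAAD", sch)
        d = dict(zip(b.names, b.values))
        assert d["GD[HP]_Dist_g1_first"] == 0.25
        assert d["GD[HP]_Dist_g1_last"] == 0.75
        assert d["GD[HP]_Dist_g2_first"] == 1.0
        assert d["GD[HP]_Dist_g2_last"] == 1.0

    def test_absent_symbol_zeros(self):
        sch = get_scheme("HP")
        b = global_descriptor("AAAA", sch)  # group 2 never occurs
        d = dict(zip(b.names, b.values))
        assert all(d[f"GD[HP]_Dist_g2_{p}"] == 0.0
                   for p in ("first", "q25", "q50", "q75", "last"))

    def test_all_schemes_total(self):
        b = gd_all("ACDEFGHIKLMNPQRSTVWY" * 3)
        expected = sum(s.k + s.k * (s.k - 1) // 2 + 5 * s.k for s in list_schemes("all"))
        assert len(b.values) == expected


class TestLZCFeatures:
    def test_one_feature_per_scheme(self):
        b = lzc_features("ACDEFGHIKLMNPQRSTVWY" * 3)
        assert len(b.values) == 20

    def test_normalization(self):
        s = "ACDEFGHIKLMNPQRSTVWY" * 3
        raw = lzc_features(s, normalize=False)
        norm = lzc_features(s, normalize=True)
        assert np.allclose(norm.values, raw.values / len(s))
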