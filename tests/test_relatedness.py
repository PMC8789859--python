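"""Clonality index, cutoff calibration, location, breakpoints, CNV calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recurrevol import relatedness as rel
from recurrevol.types import CohortCatalog


def catalog(counts, n_total):
    return CohortCatalog(counts=counts, n_total=n_total, n_tumors=10)


K1, K2, K3 = ("1", 10, "A", "T"), ("2", 20, "C", "G"), ("3", 30, "G", "A")


class TestMutationProbability:
    def test_observed(self):
        cat = catalog({K1: 2}, 1000)
        assert rel.mutation_probability(K1, cat) == pytest.approx(0.002)

    def test_pseudo_count_for_unseen(self):
        cat = catalog({K1: 2}, 1000)
        assert rel.mutation_probability(K2, cat) == pytest.approx(0.001)

    def test_saturated(self):
        cat = catalog({K1: 1000}, 1000)
        assert rel.mutation_probability(K1, cat) == 1.0

    def test_empty_catalog(self):
        with pytest.raises(ValueError):
            rel.mutation_probability(K1, CohortCatalog(counts={}, n_total=1))


class TestClonalityIndex:
    def test_single_key_closed_form(self):
        cat = catalog({K1: 100}, 1000)  # p = 0.1 -> P(X) = 0.01 -> CI = 2
        assert rel.clonality_index([K1], cat).ci == pytest.approx(2.0)

    def test_empty_set_is_zero(self):
        cat = catalog({K1: 1}, 1000)
        res = rel.clonality_index([], cat)
        assert res.ci == 0.0 and res.n_shared == 0

    def test_two_keys_sum(self):
        cat = catalog({K1: 10, K2: 100}, 1000)  # p = 0.01, 0.1 -> CI = 4 + 2
        assert rel.clonality_index([K1, K2], cat).ci == pytest.approx(6.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 999), min_size=0, max_size=20))
    def test_additivity_over_disjoint_sets(self, counts):
        keys = [("1", i + 1, "A", "T") for i in range(len(counts))]
        cat = catalog(dict(zip(keys, counts)), max(1000, sum(counts)))
        half = len(keys) // 2
        ci_all = rel.clonality_index(keys, cat).ci
        ci_split = rel.clonality_index(keys[:half], cat).ci + rel.clonality_index(keys[half:], cat).ci
        assert ci_split == pytest.approx(ci_all, abs=1e-9)

    def test_matches_exact_integer_bruteforce(self):
        rng = np.random.default_rng(5)
        keys = [("1", i + 1, "A", "T") for i in range(50)]
        counts = {k: int(c) for k, c in zip(keys, rng.integers(1, 5000, len(keys)))}
        n_total = 1_000_000
        cat = catalog(counts, n_total)
        ci = rel.clonality_index(keys, cat).ci
        # exact product via big integers: prod(c^2) / N^(2M)
        num = math.prod(c * c for c in counts.values())
        ci_exact = -(math.log10(num) - 2 * len(keys) * math.log10(n_total))
        assert ci == pytest.approx(ci_exact, abs=1e-9)


class TestClassification:
    def test_large_ci_is_ancestral(self):
        assert rel.classify_recurrence(883.2, 36.59) == "ancestral"

    def test_small_ci_is_de_novo(self):
        assert rel.classify_recurrence(12.0, 36.59) == "de_novo"

    def test_tie_goes_ancestral(self):
        assert rel.classify_recurrence(36.59, 36.59) == "ancestral"


class TestCalibration:
    def test_design_pair_counts(self):
        rng = np.random.default_rng(0)
        sets = [rng.choice(10_000, 300, replace=False) for _ in range(5)]
        cal = rel.calibrate_ci_cutoff(sets, repeats=2, seed=1)
        assert cal.n_positive_pairs == 15  # 3 fractions x 5 tumors
        assert cal.n_negative_pairs == 15
        assert len(cal.cutoffs) == 2

    def test_separable_classes_give_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        # fully private tumors: subsample pairs share many keys, random pairs none
        sets = [rng.choice(10_000_000, 500, replace=False) for _ in range(8)]
        cal = rel.calibrate_ci_cutoff(sets, repeats=5, seed=2)
        assert cal.accuracy == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        sets = [rng.choice(100_000, 200, replace=False) for _ in range(6)]
        a = rel.calibrate_ci_cutoff(sets, repeats=5, seed=4).cutoff
        b = rel.calibrate_ci_cutoff(sets[::-1], repeats=5, seed=4).cutoff
        assert a == pytest.approx(b)

    def test_needs_two_tumors(self):
        with pytest.raises(ValueError):
            rel.calibrate_ci_cutoff([np.arange(5)])


class TestLocation:
    def test_same_segment_local(self):
        assert rel.hepatic_segment_interval({6}, {6}) == 0
        assert rel.classify_location(0).location == "local"

    def test_adjacent_local(self):
        assert rel.hepatic_segment_interval({5, 6}, {7, 8}) == 1
        assert rel.classify_location(1).location == "local"

    def test_distant(self):
        assert rel.hepatic_segment_interval({6}, {3}) == 3
        assert rel.classify_location(3).location == "distant"

    def test_cap_at_four(self):
        assert rel.hepatic_segment_interval({1}, {8}) == 4

    def test_segment_bounds(self):
        with pytest.raises(ValueError):
            rel.hepatic_segment_interval({0}, {3})
        with pytest.raises(ValueError):
            rel.hepatic_segment_interval({3}, set())


class TestBreakpoints:
    def bp(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["type", "chrom1", "pos1", "chrom2", "pos2"])

    def test_identical_match(self):
        a = self.bp([("SV", "1", 100, "2", 200)])
        assert rel.shared_breakpoints(a, a.copy()) == 1

    def test_tolerance_boundary(self):
        a = self.bp([("SV", "1", 100, "2", 200)])
        b = self.bp([("SV", "1", 111, "2", 200)])
        assert rel.shared_breakpoints(a, b, tolerance_bp=10) == 0
        b2 = self.bp([("SV", "1", 110, "2", 200)])
        assert rel.shared_breakpoints(a, b2, tolerance_bp=10) == 1

    def test_order_invariance(self):
        a = self.bp([("SV", "1", 100, "2", 200), ("SV", "3", 5, "3", 900)])
        b = self.bp([("SV", "3", 5, "3", 900), ("SV", "1", 100, "2", 200)])
        assert rel.shared_breakpoints(a, b) == rel.shared_breakpoints(a.iloc[::-1], b) == 2

    def test_type_must_match(self):
        a = self.bp([("SV", "1", 100, "2", 200)])
        b = self.bp([("HBV", "1", 100, "2", 200)])
        assert rel.shared_breakpoints(a, b) == 0


class TestPloidyAndCnv:
    def test_wgd_threshold_strict(self):
        assert rel.call_wgd(3.3)
        assert not rel.call_wgd(2.9)
        assert rel.call_wgd(2.9000001)

    def test_gene_cnv_classes(self):
        assert rel.classify_gene_cnv(5, 2.0) == "amplification"
        assert rel.classify_gene_cnv(4, 2.0) == "gain"  # not "more than twice"
        assert rel.classify_gene_cnv(0, 2.0) == "deletion"
        assert rel.classify_gene_cnv(1, 2.0) == "loss"
        assert rel.classify_gene_cnv(2, 2.0) == "neutral"

    def test_negative_cn_rejected(self):
        with pytest.raises(ValueError):
            rel.classify_gene_cnv(-1, 2.0)
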