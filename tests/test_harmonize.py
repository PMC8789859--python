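"""Harmonization rules: filters, CNV drop, force calling, sharing stats."""

import numpy as np
import pytest

from recurrevol import harmonize as hz
from recurrevol.simulate import simulate_case

from conftest import make_case


class TestHighConfidenceFilter:
    def test_boundary_keep(self):
        # tumor 5/95 (VAF exactly 5%, 5 alt reads), clean deep normal
        case = make_case([("1", 100, "silent", 5, 95, True, 0, 50, False)])
        keep = hz.filter_high_confidence(case)
        assert keep[0, 0]

    def test_few_alt_reads_dropped(self):
        case = make_case([("1", 100, "silent", 2, 98, True, 0, 50, False)])
        assert not hz.filter_high_confidence(case)[0, 0]

    def test_normal_vaf_boundary_is_strict(self):
        # normal 1/99 = exactly 1%: "less than 1%" excludes it
        case = make_case([("1", 100, "silent", 10, 90, True, 0, 50, False, 1, 99)])
        assert not hz.filter_high_confidence(case)[0, 0]

    def test_shallow_normal_excluded(self):
        case = make_case([("1", 100, "silent", 10, 90, True, 0, 50, False, 0, 5)])
        assert not hz.filter_high_confidence(case)[0, 0]

    def test_shallow_tumor_excluded(self):
        case = make_case([("1", 100, "silent", 3, 6, True, 0, 50, False)])
        assert not hz.filter_high_confidence(case)[0, 0]


class TestCnvDrop:
    def loss_case(self, recurrent_cn):
        segs = [("R", "1", 1, 1000, recurrent_cn), ("T", "1", 1, 1000, 2)]
        return make_case(
            [("1", 100, "silent", 30, 70, True, 0, 54, False)], segments=segs
        )

    def test_absent_sample_in_loss_region_drops_everywhere(self):
        case = self.loss_case(1)
        final = hz.harmonize_case(case)
        assert all(len(s) == 0 for s in final.final_sets().values())
        assert (final.status == hz.CNV_DROPPED).any()

    def test_normal_copy_number_retains(self):
        case = self.loss_case(2)
        final = hz.harmonize_case(case)
        assert len(final.final_sets()["T"]) == 1

    def test_present_in_both_not_triggered(self):
        segs = [("R", "1", 1, 1000, 1), ("T", "1", 1, 1000, 2)]
        case = make_case([("1", 100, "silent", 30, 70, True, 25, 75, True)], segments=segs)
        final = hz.harmonize_case(case)
        assert len(final.final_sets()["T"]) == 1
        assert len(final.final_sets()["R"]) == 1


class TestForceCalling:
    @pytest.mark.parametrize(
        "alt, ref, recovered",
        [(2, 18, True), (3, 6, False), (1, 199, False)],
    )
    def test_thresholds(self, alt, ref, recovered):
        # called confidently in the primary; sub-threshold support in recurrent
        case = make_case([("1", 100, "silent", 30, 70, True, alt, ref, False)])
        final = hz.harmonize_case(case)
        j = final.tumor_samples.index("R")
        assert (final.status[0, j] == hz.FORCE_CALLED) == recovered

    def test_force_calling_never_removes(self):
        case = make_case(
            [
                ("1", 100, "silent", 30, 70, True, 2, 50, False),
                ("1", 200, "silent", 30, 70, True, 0, 50, False),
            ]
        )
        hc = hz.filter_high_confidence(case)
        status = np.where(hc, hz.CALLED, hz.ABSENT).astype(np.int8)
        after = hz.apply_force_calling(case, status)
        assert np.all(after >= status)


def test_shared_fraction_hand_count():
    a = np.arange(100)
    b = np.arange(75, 125)
    f_a, f_b, f_mean = hz.shared_fraction(a, b)
    assert (f_a, f_b, f_mean) == (0.25, 0.5, 0.375)
    assert hz.jaccard(a, b) == pytest.approx(25 / 125)


def test_shared_fraction_identity_and_disjoint():
    a = np.array([1, 2, 3])
    assert hz.shared_fraction(a, a) == (1.0, 1.0, 1.0)
    assert hz.jaccard(a, a) == 1.0
    b = np.array([4, 5])
    assert hz.shared_fraction(a, b) == (0.0, 0.0, 0.0)
    assert hz.jaccard(a, b) == 0.0
    assert hz.shared_fraction(np.array([]), b)[2] == 0.0


def test_shared_partition():
    shared, pa, pb = hz.shared_partition(np.array([1, 2, 3]), np.array([3, 4]))
    assert shared.tolist() == [3] and pa.tolist() == [1, 2] and pb.tolist() == [4]


class TestRandomPairNull:
    def test_pair_counts(self):
        sets = [np.arange(i, i + 10) for i in range(0, 50, 10)]
        assert len(hz.random_pair_null(sets)) == 10  # C(5,2)

    def test_identical_duplicates_reach_one(self):
        sets = [np.arange(10), np.arange(10), np.arange(100, 110)]
        null = hz.random_pair_null(sets)
        assert 1.0 in null.tolist()

    def test_needs_two(self):
        with pytest.raises(ValueError):
            hz.random_pair_null([np.arange(3)])


def test_audit_replay_reproduces_status(ancestral_case):
    case, _ = ancestral_case
    final = hz.harmonize_case(case)
    replayed = hz.replay_audit(len(case.mutations), final.tumor_samples, final.audit)
    assert np.array_equal(replayed, final.status)


def test_cnv_drop_never_increases_and_force_never_decreases(ancestral_case):
    case, _ = ancestral_case
    hc = hz.filter_high_confidence(case)
    s0 = np.where(hc, hz.CALLED, hz.ABSENT).astype(np.int8)
    s1 = hz.apply_cnv_drop(case, s0)
    present0 = s0 >= hz.CALLED
    present1 = (s1 == hz.CALLED) | (s1 == hz.FORCE_CALLED)
    assert not np.any(present1 & ~present0)
    s2 = hz.apply_force_calling(case, s1)
    present2 = (s2 == hz.CALLED) | (s2 == hz.FORCE_CALLED)
    assert not np.any(present1 & ~present2)


def test_force_calling_monotonicity_on_simulated_cases(small_params):
    """Mean shared fraction can only grow when sub-threshold sites are recovered."""
    rng = np.random.default_rng(31)
    for i in range(6):
        pattern = "ancestral" if i % 2 else "de_novo"
        case, _ = simulate_case(pattern, small_params, rng, f"P{i}")
        final = hz.harmonize_case(case)
        roles = {p.sample: p.role for p in case.profiles}
        sets = final.final_sets()
        called_only = final.status == hz.CALLED
        def union(role, matrix=None):
            cols = [j for j, s in enumerate(final.tumor_samples) if roles[s] == role]
            if matrix is None:
                return np.unique(np.concatenate([sets[final.tumor_samples[j]] for j in cols]))
            return np.unique(np.concatenate([np.flatnonzero(matrix[:, j]) for j in cols]))
        f_after = hz.shared_fraction(union("primary"), union("recurrent"))[2]
        f_before = hz.shared_fraction(
            union("primary", called_only), union("recurrent", called_only)
        )[2]
        assert f_after >= f_before
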