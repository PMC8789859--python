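"""Synthetic cohort generator: clone trees, CCFs, reads, catalogs, cases."""

import numpy as np
import pytest

from recurrevol import harmonize as hz
from recurrevol import signatures as sig
from recurrevol.simulate import (
    SimulationParams,
    assign_sample_ccfs,
    simulate_case,
    simulate_catalog,
    simulate_clone_tree,
    simulate_reads,
    write_case_files,
    zipf_draws,
)


class TestCloneTree:
    def test_single_node(self):
        assert simulate_clone_tree(1, 0).tolist() == [-1]

    def test_seeded_determinism(self):
        assert simulate_clone_tree(5, 42).tolist() == simulate_clone_tree(5, 42).tolist()

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            simulate_clone_tree(0, 0)

    def test_rooted_acyclic_over_many_seeds(self):
        for s in range(1000):
            parents = simulate_clone_tree(1 + s % 7, s)
            assert parents[0] == -1
            assert (parents[1:] < np.arange(1, len(parents))).all()  # acyclic by construction
            assert (parents[1:] >= 0).all()  # single root


class TestSampleCcfs:
    def test_pigeonhole_sums_hold(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(1, 7))
            parents = simulate_clone_tree(k, rng)
            presence = np.ones((k, 2), dtype=bool)
            ccf = assign_sample_ccfs(parents, presence, rng, min_separation=0.1)
            assert np.allclose(ccf[0], 1.0)
            for v in range(k):
                kids = np.flatnonzero(parents == v)
                if len(kids):
                    assert (ccf[kids].sum(axis=0) <= ccf[v] + 1e-9).all()

    def test_absent_samples_get_zero(self):
        parents = np.array([-1, 0])
        presence = np.array([[True, True], [True, False]])
        ccf = assign_sample_ccfs(parents, presence, np.random.default_rng(1))
        assert ccf[1, 1] == 0.0 and ccf[1, 0] > 0


class TestSimulateReads:
    def test_zero_ccf_no_alt_reads(self):
        alt, _ = simulate_reads(np.zeros(100), 0.8, np.full(100, 2), 54, np.random.default_rng(0))
        assert (alt == 0).all()

    def test_noiseless_clonal_heterozygous_diploid(self):
        alt, ref = simulate_reads(
            np.ones(5), 1.0, np.full(5, 2), 54, np.random.default_rng(0), noiseless=True, noiseless_depth=10_000
        )
        assert (alt / (alt + ref) == 0.5).all()

    def test_mean_vaf_within_three_se(self):
        rng = np.random.default_rng(2)
        n = 10_000
        purity, cn, ccf, depth_mean = 0.6, 2, 0.5, 54
        alt, ref = simulate_reads(np.full(n, ccf), purity, np.full(n, cn), depth_mean, rng)
        evaf = purity * ccf / (2 * (1 - purity) + purity * cn)
        depth = alt + ref
        vaf = alt[depth > 0] / depth[depth > 0]
        se = np.sqrt(evaf * (1 - evaf) / depth[depth > 0]).mean() / np.sqrt(len(vaf))
        assert abs(vaf.mean() - evaf) < 3 * se * np.sqrt(1 + depth_mean / depth.mean())

    def test_cn_zero_with_ccf_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads(np.array([0.5]), 0.5, np.array([0]), 54, np.random.default_rng(0))

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            simulate_reads(np.array([0.5]), 0.0, np.array([2]), 54, np.random.default_rng(0))


class TestCatalog:
    def test_conservation(self):
        cat, sets, _ = simulate_catalog(20, 300, 1.5, seed=0)
        assert cat.n_total == sum(len(s) for s in sets)
        assert cat.n_tumors == 20
        assert sum(cat.counts.values()) == cat.n_total

    def test_degenerate_s_shares_single_hotspot(self):
        _, sets, _ = simulate_catalog(5, 100, 1e9, seed=1, hotspot_fraction=0.1)
        shared = set(sets[0])
        for s in sets[1:]:
            shared &= set(s)
        assert len(shared) == 1

    def test_zipf_rank_frequency_slope(self):
        rng = np.random.default_rng(7)
        draws = zipf_draws(1.5, 100_000, rng)
        ranks, counts = np.unique(draws, return_counts=True)
        order = np.argsort(-counts)
        freq = counts[order]
        keep = freq >= 5
        x = np.log(np.arange(1, keep.sum() + 1))
        y = np.log(freq[keep])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.2)

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            zipf_draws(0.5, 10, np.random.default_rng(0))


class TestSimulatedCases:
    def test_de_novo_raw_sharing_below_five_percent(self, small_params):
        for s in range(3):
            case, _ = simulate_case("de_novo", small_params, np.random.default_rng(100 + s), "P")
            keys = case.keys()
            called = case.called
            prim = set(keys[called[:, 0]])
            rec = set(keys[called[:, 1]])
            shared = len(prim & rec)
            f_mean = (shared / max(len(prim), 1) + shared / max(len(rec), 1)) / 2
            assert f_mean <= 0.05

    def test_ancestral_sharing_in_target_band(self, small_params):
        case, truth = simulate_case("ancestral", small_params, np.random.default_rng(11), "P")
        assert 0.25 <= truth.shared_fraction <= 0.80

    def test_hypermutator_burden_and_spectrum(self):
        params = SimulationParams(hypermutator_prob=1.0, seed=0)
        case, truth = simulate_case("ancestral", params, np.random.default_rng(3), "P")
        assert truth.hypermutator
        # burden of mutations truly present in the primary tumor
        primary = case.tumor_samples[0]
        present = np.zeros(len(case.mutations), dtype=bool)
        for i, cid in enumerate(truth.cluster_ids):
            if truth.cluster_ccfs.at[cid, primary] > 0:
                present |= truth.mut_cluster == i
        assert sig.hypermutation_flag(int(present.sum()))
        spec = sig.spectrum(case.mutations)
        assert spec.counts6.idxmax() == "T>A"

    def test_same_seed_byte_identical_files(self, tmp_path, small_params):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d, seed in ((d1, 5), (d2, 5)):
            case, truth = simulate_case("ancestral", small_params, np.random.default_rng(seed), "P")
            write_case_files(case, truth, d)
        for name in ("mutations.tsv", "segments.tsv", "manifest.yaml", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_positions_inside_genome(self, ancestral_case):
        case, _ = ancestral_case
        assert (case.mutations["pos"] >= 1).all()
        assert case.mutations["chrom"].isin([str(i) for i in range(1, 23)]).all()

    def test_planted_cnv_drop_exercised(self, ancestral_case):
        case, truth = ancestral_case
        assert truth.planted_cnv_drop.sum() > 0
        final = hz.harmonize_case(case)
        dropped_rows = np.flatnonzero((final.status == hz.CNV_DROPPED).any(axis=1))
        planted = np.flatnonzero(truth.planted_cnv_drop)
        # every planted mutation the caller saw is excluded; none survive
        assert len(np.intersect1d(planted, dropped_rows)) > 0
        survivors = np.unique(np.concatenate(list(final.final_sets().values())))
        assert len(np.intersect1d(planted, survivors)) == 0

    def test_noiseless_truth_consistency(self):
        """At noiseless depth the harmonized sets match the truth-derived
        expectation exactly (deterministic caller rule applied to truth)."""
        from recurrevol.io import local_copy_number_batch

        params = SimulationParams(
            mutations_per_tumor=(2_000, 6_000), burden_log_mean=np.log(3_000.0),
            noiseless=True, seed=0,
        )
        case, truth = simulate_case("ancestral", params, np.random.default_rng(21), "P")
        final = hz.harmonize_case(case)
        sets = final.final_sets()
        chroms = case.mutations["chrom"].to_numpy(dtype=object)
        pos = case.mutations["pos"].to_numpy(np.int64)
        n = len(case.mutations)
        tumor = final.tumor_samples
        # per-mutation true CCF per sample from the truth labels
        ccf = np.zeros((n, len(tumor)))
        for i, cid in enumerate(truth.cluster_ids):
            members = truth.mut_cluster == i
            for j, s in enumerate(tumor):
                ccf[members, j] = truth.cluster_ccfs.at[cid, s]
        decoy = truth.mut_cluster == -2
        for j, s in enumerate(tumor):
            if case.profile(s).role == "primary":
                ccf[decoy, j] = 0.999
        evaf = np.zeros_like(ccf)
        cn_all = np.zeros_like(ccf)
        for j, s in enumerate(tumor):
            prof = case.profile(s)
            seg = case.segments[s]
            cn = local_copy_number_batch(seg, chroms, pos, fallback=int(round(prof.ploidy)))
            cn_all[:, j] = cn
            ccf_here = np.where(cn == 0, 0.0, ccf[:, j])
            evaf[:, j] = prof.purity * ccf_here / (2 * (1 - prof.purity) + prof.purity * np.maximum(cn, 1))
        depth = params.noiseless_depth
        called = evaf >= 0.05  # noiseless caller: alt and depth thresholds trivially met
        any_called = called.any(axis=1)
        # CNV drop: called somewhere, absent in a sample whose locus is lost
        drop = (any_called[:, None] & ~called & (cn_all <= 1)).any(axis=1)
        aggregate = any_called & ~drop
        recovered = np.rint(depth * evaf) >= 2
        expected = {
            s: np.flatnonzero(aggregate & (called[:, j] | recovered[:, j]))
            for j, s in enumerate(tumor)
        }
        for s in tumor:
            assert np.array_equal(sets[s], expected[s]), s

    def test_multi_region_polyclonal_structure(self):
        params = SimulationParams(
            multi_region=True, n_regions=(3, 3),
            mutations_per_tumor=(2_000, 6_000), burden_log_mean=np.log(3_000.0), seed=0,
        )
        case, truth = simulate_case("ancestral", params, np.random.default_rng(8), "P")
        assert truth.polyclonal
        recurrent = [p.sample for p in case.profiles if p.role == "recurrent"]
        subclonal = 0
        for cid in truth.cluster_ids:
            if truth.cluster_category[cid] != "trunk_subclone":
                continue
            row = truth.cluster_ccfs.loc[cid, recurrent]
            if (row.between(0.05, 0.8)).sum() >= 2:
                subclonal += 1
        assert subclonal >= 2
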