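"""Pigeonhole tree construction, brute-force oracle, drivers, heterogeneity."""

import numpy as np
import pandas as pd
import pytest

from recurrevol import evolution as ev
from recurrevol.ccf import MutationCluster, CategoryAssignment
from recurrevol.simulate import simulate_clone_tree, assign_sample_ccfs

from conftest import make_case


def clusters_from(ccf_matrix, sizes=None, samples=None):
    ccf_matrix = np.asarray(ccf_matrix, dtype=float)
    k, n_s = ccf_matrix.shape
    samples = samples or [f"S{j}" for j in range(n_s)]
    sizes = sizes or [100] * k
    return [
        MutationCluster(
            cluster_id=f"K{i}",
            member_rows=np.arange(sizes[i]),
            ccf=pd.Series(ccf_matrix[i], index=samples),
            size=sizes[i],
            silent_only=False,
        )
        for i in range(k)
    ]


class TestPigeonholeRules:
    def test_sum_above_one_forces_chain(self):
        # one sample, CCFs 1.0 / 0.6 / 0.5: the two subclones sum above the
        # root so they cannot be siblings
        cl = clusters_from([[1.0], [0.6], [0.5]])
        tree = ev.build_subclonal_architecture(cl)
        assert tree.parents == {"K0": None, "K1": "K0", "K2": "K1"}

    def test_chain_is_unique_valid_topology(self):
        valid = ev.enumerate_valid_trees(np.array([[1.0], [0.6], [0.5]]), eps=0.05)
        assert valid == {(-1, 0, 1)}

    def test_reversed_ccfs_force_branching(self):
        cl = clusters_from([[1.0, 1.0], [0.6, 0.2], [0.2, 0.6]])
        tree = ev.build_subclonal_architecture(cl)
        assert tree.parents["K1"] == "K0" and tree.parents["K2"] == "K0"

    def test_single_cluster_root_only(self):
        cl = clusters_from([[0.9, 0.8]])
        tree = ev.build_subclonal_architecture(cl)
        assert tree.parents == {"K0": None}

    def test_infeasible_raises_and_enumerates_empty(self):
        # "child" exceeds every putative parent in every sample
        ccf = np.array([[0.5, 0.5], [0.9, 0.9], [0.9, 0.2]])
        assert ev.enumerate_valid_trees(ccf, eps=0.01) == set()
        with pytest.raises(ValueError):
            ev.build_subclonal_architecture(clusters_from(ccf), eps=0.01)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError):
            ev.enumerate_valid_trees(np.zeros((7, 2)))

    def test_oracle_membership_random_configs(self):
        """Greedy construction always lands inside the brute-force valid set."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 60:
            k = int(rng.integers(2, 6))
            parents = simulate_clone_tree(k, rng)
            presence = np.ones((k, 2), dtype=bool)
            ccf = assign_sample_ccfs(parents, presence, rng, min_separation=0.1)
            cl = clusters_from(ccf)
            valid = ev.enumerate_valid_trees(ccf, eps=0.05)
            assert len(valid) > 0  # truth itself is feasible
            tree = ev.build_subclonal_architecture(cl, eps=0.05)
            built = tuple(
                -1 if tree.parents[f"K{i}"] is None else int(tree.parents[f"K{i}"][1:])
                for i in range(k)
            )
            assert built in valid
            if len(valid) == 1:
                truth = tuple(int(p) for p in parents)
                assert built == truth
            checked += 1


class TestPhylogeny:
    def test_relative_lengths(self):
        cl = clusters_from([[1.0], [0.5]], sizes=[5_000, 2_500])
        tree = ev.build_subclonal_architecture(cl)
        phylo = ev.build_phylogeny(tree, primary_total=10_000)
        lengths = phylo.branch_lengths()
        assert lengths == {"K0": 0.5, "K1": 0.25}
        assert "K1:0.25" in phylo.newick(relative=True)

    def test_path_additivity(self):
        cl = clusters_from([[1.0], [0.6], [0.4]], sizes=[100, 60, 40])
        phylo = ev.build_phylogeny(ev.build_subclonal_architecture(cl), 200)
        lengths = phylo.branch_lengths()
        path = lengths["K0"] + lengths["K1"] + lengths["K2"]
        assert path == pytest.approx(200 / 200)

    def test_zero_total_rejected(self):
        cl = clusters_from([[1.0]])
        with pytest.raises(ValueError):
            ev.build_phylogeny(ev.build_subclonal_architecture(cl), 0)


class TestHeterogeneity:
    def test_identical_regions_zero(self):
        assert ev.pairwise_heterogeneity(np.arange(10), np.arange(10)) == 0.0

    def test_disjoint_regions_one(self):
        assert ev.pairwise_heterogeneity(np.arange(10), np.arange(10, 20)) == 1.0

    def test_spatial_temporal_split(self):
        sets = {
            "T1": np.arange(0, 100),
            "T2": np.arange(0, 100),
            "R1": np.arange(50, 150),
        }
        roles = {"T1": "primary", "T2": "primary", "R1": "recurrent"}
        het = ev.spatial_temporal_ith(sets, roles)
        assert het.spatial_mean == 0.0
        assert het.temporal_mean == pytest.approx(1 - 50 / 150)

    def test_absent_means_when_no_pairs(self):
        het = ev.spatial_temporal_ith({"T1": np.arange(5)}, {"T1": "primary"})
        assert het.spatial_mean is None and het.temporal_mean is None


class TestPolyclonalSeeding:
    roles = {"T1": "primary", "R1": "recurrent", "R2": "recurrent"}

    def assignment(self, clusters):
        from recurrevol.ccf import classify_cluster_categories

        return classify_cluster_categories(clusters, self.roles, "multi_region")

    def test_two_subclonal_trunk_clusters_polyclonal(self):
        cl = clusters_from(
            [[1.0, 1.0, 1.0], [0.5, 0.4, 0.3], [0.3, 0.3, 0.5]],
            samples=["T1", "R1", "R2"],
        )
        det = ev.detect_polyclonal_seeding(cl, self.assignment(cl), self.roles)
        assert det["seeding"] == "polyclonal"

    def test_single_region_subclone_monoclonal(self):
        cl = clusters_from(
            [[1.0, 1.0, 1.0], [0.5, 0.4, 0.0]], samples=["T1", "R1", "R2"]
        )
        det = ev.detect_polyclonal_seeding(cl, self.assignment(cl), self.roles)
        assert det["seeding"] == "monoclonal"

    def test_recurrence_ubiquitous_flagged(self):
        cl = clusters_from(
            [[1.0, 1.0, 1.0], [0.0, 0.4, 0.5]], samples=["T1", "R1", "R2"]
        )
        det = ev.detect_polyclonal_seeding(cl, self.assignment(cl), self.roles)
        assert det["recurrence_ubiquitous_clusters"] == ["K1"]

    def test_single_recurrent_region_not_evaluable(self):
        cl = clusters_from([[1.0, 1.0]], samples=["T1", "R1"])
        with pytest.raises(ValueError):
            ev.detect_polyclonal_seeding(
                cl, self.assignment(cl), {"T1": "primary", "R1": "recurrent"}
            )


class TestDrivers:
    def driver_case(self):
        rows = [
            ("17", 7_570_000, "nonsynonymous", 30, 70, True, 28, 72, True),  # TP53 trunk
            ("17", 7_571_000, "silent", 30, 70, True, 28, 72, True),  # silent: never a driver
            ("3", 41_250_000, "nonsynonymous", 20, 80, True, 0, 100, False),  # CTNNB1 primary only
        ]
        segs = [
            ("T", "8", 1, 200_000_000, 2),
            ("R", "8", 128_000_000, 129_000_000, 9),  # MYC amplified, recurrent only
        ]
        return make_case(rows, segments=segs, genes=["TP53", "TP53", "CTNNB1"])

    def make_clusters(self):
        return [
            MutationCluster("K0", np.array([0, 1]), pd.Series({"T": 0.95, "R": 0.95}), 2, False),
            MutationCluster("K1", np.array([2]), pd.Series({"T": 0.5, "R": 0.0}), 1, False),
        ]

    def test_driver_labels(self):
        case = self.driver_case()
        clusters = self.make_clusters()
        assignment = CategoryAssignment(
            scheme="ancestral", categories={"K0": "trunk_clone", "K1": "primary_branch"}
        )
        drivers = ev.label_drivers(case, clusters, assignment)
        by_gene = {(d.gene, d.alteration): d for d in drivers}
        assert by_gene[("TP53", "mutation")].timing == "trunk_clone"
        assert by_gene[("CTNNB1", "mutation")].timing == "branch"
        assert by_gene[("MYC", "amplification")].timing == "branch"
        assert ("TP53", "silent") not in by_gene and len([d for d in drivers if d.gene == "TP53"]) == 1

    def test_unplaced_driver_warns(self):
        case = self.driver_case()
        clusters = [self.make_clusters()[1]]  # TP53 rows not in any cluster
        assignment = CategoryAssignment(scheme="ancestral", categories={"K1": "primary_branch"})
        with pytest.warns(UserWarning, match="TP53"):
            drivers = ev.label_drivers(case, clusters, assignment)
        assert any(d.timing == "unplaced" for d in drivers)

    def test_timing_summary_fractions(self):
        d1 = [ev.DriverAlteration("TP53", "mutation", "K0", "trunk_clone")]
        d2 = [ev.DriverAlteration("TP53", "mutation", "K0", "branch")]
        summary = ev.driver_timing_summary([d1, d2])
        row = summary[(summary.gene == "TP53") & (summary.timing == "trunk_clone")]
        assert row["fraction"].iloc[0] == 0.5
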