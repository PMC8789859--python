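"""Truth-recovery benchmarks on the synthetic cohort generator.

Each routine simulates data under the generator's study conditions, runs the
corresponding analysis stage, and scores it against the generator's ground
truth. They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from . import harmonize, relatedness, signatures
from .ccf import classify_cluster_categories, cluster_mutations, filter_clusters, compute_ccf, expected_vaf
from .evolution import build_subclonal_architecture, enumerate_valid_trees, spatial_temporal_ith
from .pipeline import case_clonality
from .simulate import SimulationParams, assign_sample_ccfs, simulate_case, simulate_clone_tree, simulate_cohort
from .types import CohortCatalog


def evaluate_pattern_recovery(
    n_cohorts: int = 20,
    base_seed: int = 0,
    params: Optional[SimulationParams] = None,
    calibration_repeats: int = 100,
) -> dict:
    """Classify every patient of seeded synthetic cohorts with a cutoff
    calibrated on each cohort's background catalog.

    Returns per-cohort correct-call counts, the calibrated cutoffs, and the
    per-case force-calling sharing differences (after minus before) for the
    monotonicity check.
    """
    correct_per_cohort = []
    cutoffs = []
    sharing_deltas = []
    accuracies = []
    for i in range(n_cohorts):
        p = params or SimulationParams()
        p = SimulationParams(**{**p.__dict__, "seed": base_seed + i})
        cases, truths, catalog, sets = simulate_cohort(p)
        cal = relatedness.calibrate_ci_cutoff(sets, repeats=calibration_repeats, seed=base_seed + i)
        cutoffs.append(cal.cutoff)
        accuracies.append(cal.accuracy)
        n_correct = 0
        for case, truth in zip(cases, truths):
            res = case_clonality(case, catalog, cal.cutoff)
            n_correct += res["pattern"] == truth.pattern
            sharing_deltas.append(
                res["sharing"]["f_mean"] - res["sharing"]["f_mean_before_force_calling"]
            )
        correct_per_cohort.append(n_correct)
    return {
        "n_patients": (params or SimulationParams()).n_patients,
        "correct_per_cohort": correct_per_cohort,
        "cutoffs": cutoffs,
        "calibration_accuracies": accuracies,
        "sharing_deltas": sharing_deltas,
    }


def evaluate_ci_oracle(n_sets: int = 1000, max_keys: int = 50, seed: int = 0) -> float:
    """Max |CI - exact big-integer brute force| over random shared key sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_total = 500_000
    for _ in range(n_sets):
        m = int(rng.integers(0, max_keys + 1))
        keys = [("1", int(p), "A", "T") for p in rng.choice(10**6, m, replace=False)]
        counts = {k: int(c) for k, c in zip(keys, rng.integers(1, 10_000, m))}
        catalog = CohortCatalog(counts=counts or {("1", 1, "A", "T"): 1}, n_total=n_total)
        ci = relatedness.clonality_index(keys, catalog).ci
        if m == 0:
            exact = 0.0
        else:
            num = math.prod(c * c for c in counts.values())
            exact = -(math.log10(num) - 2 * m * math.log10(n_total))
        worst = max(worst, abs(ci - exact))
    return worst


def evaluate_cluster_recovery(
    n_seeds: int = 20,
    base_seed: int = 1000,
    params: Optional[SimulationParams] = None,
    center_tol: float = 0.10,
    min_separation: float = 0.2,
) -> dict:
    """Cluster seeded ancestral cases at sequencing depth and score centers
    and categories against the truth.

    Center accuracy is scored for true clusters separated by at least
    ``min_separation`` from every other cluster (L-inf over samples); each
    true cluster is matched to the inferred cluster holding the majority of
    its mutations.
    """
    p = params or SimulationParams()
    n_center = n_center_ok = 0
    n_cat = n_cat_ok = 0
    for s in range(n_seeds):
        case, truth = simulate_case("ancestral", p, np.random.default_rng(base_seed + s), "P")
        hc = harmonize.harmonize_case(case)
        clusters = filter_clusters(cluster_mutations(hc, seed=s), len(hc.union_rows()))
        roles = {pr.sample: pr.role for pr in case.profiles}
        assign = classify_cluster_categories(clusters, roles, "ancestral")
        row_cluster = {}
        for c in clusters:
            for r in c.member_rows:
                row_cluster[int(r)] = c
        tccf = truth.cluster_ccfs.to_numpy()
        sep = np.abs(tccf[:, None, :] - tccf[None, :, :]).max(axis=2)
        np.fill_diagonal(sep, np.inf)
        for ci_idx, cid in enumerate(truth.cluster_ids):
            members = np.flatnonzero(truth.mut_cluster == ci_idx)
            if len(members) == 0:
                continue
            votes: dict = {}
            for r in members:
                c = row_cluster.get(int(r))
                if c is not None:
                    votes[c.cluster_id] = votes.get(c.cluster_id, 0) + 1
            if not votes:
                continue
            match_id = max(votes, key=votes.get)
            match = next(c for c in clusters if c.cluster_id == match_id)
            err = float(np.abs(match.ccf.to_numpy() - tccf[ci_idx]).max())
            if sep[ci_idx].min() >= min_separation:
                n_center += 1
                n_center_ok += err <= center_tol
            n_cat += 1
            n_cat_ok += assign.categories.get(match_id) == truth.cluster_category[cid]
    return {
        "center_rate": n_center_ok / max(n_center, 1),
        "center_n": n_center,
        "category_rate": n_cat_ok / max(n_cat, 1),
        "category_n": n_cat,
    }


def evaluate_noiseless_category_recovery(seed: int = 0, params: Optional[SimulationParams] = None) -> float:
    """Category recovery on a noiseless ancestral case (expected: exact)."""
    base = params or SimulationParams(
        mutations_per_tumor=(2_000, 8_000), burden_log_mean=float(np.log(4_000.0))
    )
    p = SimulationParams(**{**base.__dict__, "noiseless": True})
    case, truth = simulate_case("ancestral", p, np.random.default_rng(seed), "P")
    hc = harmonize.harmonize_case(case)
    clusters = filter_clusters(cluster_mutations(hc, seed=seed), len(hc.union_rows()))
    roles = {pr.sample: pr.role for pr in case.profiles}
    assign = classify_cluster_categories(clusters, roles, "ancestral")
    row_cluster = {}
    for c in clusters:
        for r in c.member_rows:
            row_cluster[int(r)] = c.cluster_id
    ok = tot = 0
    for ci_idx, cid in enumerate(truth.cluster_ids):
        members = np.flatnonzero(truth.mut_cluster == ci_idx)
        if len(members) == 0:
            continue
        votes: dict = {}
        for r in members:
            mid = row_cluster.get(int(r))
            if mid is not None:
                votes[mid] = votes.get(mid, 0) + 1
        if not votes:
            continue
        match = max(votes, key=votes.get)
        tot += 1
        ok += assign.categories.get(match) == truth.cluster_category[cid]
    return ok / max(tot, 1)


def evaluate_ccf_round_trip(n_points: int = 2_000, seed: int = 0) -> float:
    """Max |VAF - forward(inverse(VAF))| over random (vaf, purity, cn)."""
    rng = np.random.default_rng(seed)
    vaf = rng.uniform(0, 1, n_points)
    purity = rng.uniform(0.05, 1.0, n_points)
    cn = rng.integers(1, 9, n_points)
    worst = 0.0
    for v, p, c in zip(vaf, purity, cn):
        ccf = compute_ccf(float(v), float(p), int(c), clip=False)
        worst = max(worst, abs(float(expected_vaf(ccf, float(p), int(c))) - float(v)))
    return worst


def evaluate_pigeonhole_oracle(n_configs: int = 200, seed: int = 11, eps: float = 0.05, max_k: int = 5) -> dict:
    """Constructed architectures vs the brute-force valid-tree set."""
    from .ccf import MutationCluster

    rng = np.random.default_rng(seed)
    member = 0
    singleton = singleton_match = 0
    for _ in range(n_configs):
        k = int(rng.integers(2, max_k + 1))
        parents = simulate_clone_tree(k, rng)
        presence = np.ones((k, 2), dtype=bool)
        ccf = assign_sample_ccfs(parents, presence, rng, min_separation=0.1)
        clusters = [
            MutationCluster(f"K{i}", np.arange(10), pd.Series(ccf[i], index=["A", "B"]), 10, False)
            for i in range(k)
        ]
        valid = enumerate_valid_trees(ccf, eps=eps)
        tree = build_subclonal_architecture(clusters, eps=eps)
        built = tuple(
            -1 if tree.parents[f"K{i}"] is None else int(tree.parents[f"K{i}"][1:])
            for i in range(k)
        )
        member += built in valid
        if len(valid) == 1:
            singleton += 1
            singleton_match += built == tuple(int(x) for x in parents)
    return {
        "membership_rate": member / n_configs,
        "n_singleton": singleton,
        "singleton_match_rate": singleton_match / max(singleton, 1),
    }


def evaluate_signature_refit(n_mutations: int = 5_000, seed: int = 0) -> float:
    """Max per-weight error refitting a sampled three-signature mixture."""
    S = signatures.synthetic_reference_signatures()
    rng = np.random.default_rng(seed)
    true_w = {"Signature.4": 0.5, "Signature.22": 0.3, "Signature.5": 0.2}
    w = np.zeros(S.shape[1])
    for name, v in true_w.items():
        w[S.columns.get_loc(name)] = v
    q = S.to_numpy() @ w
    counts = np.bincount(rng.choice(96, n_mutations, p=q / q.sum()), minlength=96)
    exp = signatures.refit_exposures(counts, S)
    return max(abs(float(exp.weights[k]) - v) for k, v in true_w.items())


def evaluate_trunk_signature_enrichment(
    n_patients: int = 20, base_seed: int = 40, params: Optional[SimulationParams] = None
) -> dict:
    """Trunk vs branch signature-22 exposure on cases with a trunk-only
    aristolochic-acid-like etiology planted.

    Categories are taken from the generator's truth so the comparison
    isolates the spectrum/refit stage.
    """
    base = params or SimulationParams()
    p = SimulationParams(**{**base.__dict__, "trunk_s22": True, "hypermutator_prob": 0.0})
    S = signatures.synthetic_reference_signatures()
    n_enriched = 0
    for i in range(n_patients):
        case, truth = simulate_case("ancestral", p, np.random.default_rng(base_seed + i), "P")
        trunk_rows, branch_rows = [], []
        for ci_idx, cid in enumerate(truth.cluster_ids):
            rows = np.flatnonzero(truth.mut_cluster == ci_idx)
            if truth.cluster_category[cid] in ("trunk_clone", "trunk_subclone"):
                trunk_rows.append(rows)
            else:
                branch_rows.append(rows)
        exposures = {}
        for name, groups in (("trunk", trunk_rows), ("branch", branch_rows)):
            rows = np.concatenate(groups)
            muts = case.mutations.iloc[rows]
            muts = muts[muts["variant_class"] == "SNV"]
            spec = signatures.spectrum(muts, with_context=True)
            exposures[name] = signatures.refit_exposures(spec.counts96, S).weights["Signature.22"]
        n_enriched += exposures["trunk"] > exposures["branch"]
    return {"n_enriched": n_enriched, "n_patients": n_patients}


def evaluate_heterogeneity_direction(
    n_seeds: int = 20, base_seed: int = 70, params: Optional[SimulationParams] = None
) -> dict:
    """Temporal vs spatial heterogeneity on multi-region ancestral cases."""
    base = params or SimulationParams()
    p = SimulationParams(**{**base.__dict__, "multi_region": True})
    n_ok = 0
    for i in range(n_seeds):
        case, _ = simulate_case("ancestral", p, np.random.default_rng(base_seed + i), "P")
        hc = harmonize.harmonize_case(case)
        roles = {pr.sample: pr.role for pr in case.profiles}
        het = spatial_temporal_ith(hc.final_sets(), roles)
        n_ok += het.temporal_mean > het.spatial_mean
    return {"n_temporal_greater": n_ok, "n_seeds": n_seeds}


def evaluate_calibration_bookkeeping(n_tumors: int = 200, seed: int = 0) -> dict:
    """Design counts of the calibration and the random-pair null."""
    from .simulate import simulate_catalog

    _, sets, _ = simulate_catalog(n_tumors, 1_000, 1.5, seed=seed)
    cal = relatedness.calibrate_ci_cutoff(sets[:n_tumors], repeats=1, seed=seed)
    _, sets40, _ = simulate_catalog(40, 1_000, 1.5, seed=seed + 1)
    null = harmonize.random_pair_null(sets40)
    return {
        "n_positive_pairs": cal.n_positive_pairs,
        "n_negative_pairs": cal.n_negative_pairs,
        "n_random_pairs_40": int(len(null)),
        "null_max": float(null.max()),
    }
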