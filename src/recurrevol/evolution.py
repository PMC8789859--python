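"""Subclonal architectures, phylogenies, driver timing and heterogeneity.

Tree construction follows the pigeonhole principle over per-sample cluster
CCFs: a parent must dominate each child in every sample (a descendant
cannot outnumber its ancestor's cells), and the children of any node can
never jointly exceed it (two subclones whose CCFs sum above their common
ancestor's CCF must be nested, not siblings). Within tolerance ``eps``
these two constraints encode the linear/branching rules: clusters whose
CCFs sum above 1 are forced onto one lineage, clusters whose relative CCFs
reverse between samples are forced onto separate branches.

``build_subclonal_architecture`` inserts clusters greedily in decreasing
total-CCF order with deterministic tie-breaking and backtracking;
``enumerate_valid_trees`` is the brute-force oracle over all rooted trees
(small cluster counts only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ccf import MutationCluster, CategoryAssignment
from .harmonize import jaccard
from .io import local_copy_number_batch, tree_to_newick
from .relatedness import classify_gene_cnv
from .simulate import DRIVER_GENES
from .types import PatientCase


@dataclass
class CloneTree:
    """Rooted clone tree: parent links plus per-node CCFs and sizes."""

    parents: dict[str, Optional[str]]
    ccf: pd.DataFrame  # clusters x samples
    sizes: dict[str, int]
    scale: int = 0  # total mutations in the primary tumor

    def newick(self, relative: bool = False) -> str:
        lengths = {
            k: (v / self.scale if relative and self.scale else v)
            for k, v in self.sizes.items()
        }
        return tree_to_newick(self.parents, lengths)

    def branch_lengths(self) -> dict[str, float]:
        if self.scale <= 0:
            raise ValueError("primary mutation total must be positive")
        return {k: v / self.scale for k, v in self.sizes.items()}


@dataclass
class DriverAlteration:
    gene: str
    alteration: str  # mutation | promoter_mutation | amplification | deletion | sv_breakpoint
    node: Optional[str]  # cluster id for mutations, None for CNV/SV
    timing: str  # trunk_clone | trunk_subclone | branch | clone | subclone | unplaced
    samples: tuple[str, ...] = ()


@dataclass
class HeterogeneityResult:
    pairwise: pd.DataFrame  # columns: sample_a, sample_b, kind, dissimilarity
    spatial_mean: Optional[float]
    temporal_mean: Optional[float]


# ---------------------------------------------------------------------------
# pigeonhole construction


def _constraints_ok(parent_ccf, child_ccf, eps):
    return bool(np.all(parent_ccf >= child_ccf - eps))


def _valid_tree(parents: np.ndarray, ccf: np.ndarray, eps: float) -> bool:
    k = ccf.shape[0]
    for v in range(k):
        p = parents[v]
        if p >= 0 and not _constraints_ok(ccf[p], ccf[v], eps):
            return False
    for p in range(k):
        kids = np.flatnonzero(parents == p)
        if len(kids) and np.any(ccf[kids].sum(axis=0) > ccf[p] + eps):
            return False
    return True


def build_subclonal_architecture(
    clusters: Sequence[MutationCluster],
    eps: float = 0.05,
) -> CloneTree:
    """Deterministic pigeonhole tree over filtered clusters.

    Clusters are inserted in decreasing total-CCF order (ties: larger size,
    then lexicographic id); each attaches to the feasible already-inserted
    parent with the largest minimum CCF margin (ties: larger size, then
    lexicographic id), backtracking when a later insertion becomes
    infeasible. Raises with the violated constraints when no valid tree
    exists within ``eps``.
    """
    if not clusters:
        raise ValueError("no clusters to arrange")
    ids = [c.cluster_id for c in clusters]
    ccf = np.vstack([c.ccf.to_numpy() for c in clusters])
    sizes = np.array([c.size for c in clusters])
    order = sorted(
        range(len(ids)), key=lambda i: (-float(ccf[i].sum()), -int(sizes[i]), ids[i])
    )
    root = order[0]
    for i in order[1:]:
        if not _constraints_ok(ccf[root], ccf[i], eps):
            raise ValueError(
                f"no unique maximal cluster: {ids[root]} does not dominate {ids[i]}"
            )
    parents = np.full(len(ids), -2, dtype=np.int64)  # -2 = not inserted
    parents[root] = -1
    child_sum = np.zeros_like(ccf)

    def feasible_parents(v):
        cands = []
        for u in range(len(ids)):
            if parents[u] == -2 or u == v:
                continue
            if not _constraints_ok(ccf[u], ccf[v], eps):
                continue
            if np.any(child_sum[u] + ccf[v] > ccf[u] + eps):
                continue
            margin = float(np.min(ccf[u] - ccf[v]))
            cands.append((-margin, -int(sizes[u]), ids[u], u))
        return [u for *_, u in sorted(cands)]

    def attach(pos: int) -> bool:
        if pos == len(order):
            return True
        v = order[pos]
        for u in feasible_parents(v):
            parents[v] = u
            child_sum[u] += ccf[v]
            if attach(pos + 1):
                return True
            child_sum[u] -= ccf[v]
            parents[v] = -2
        return False

    if not attach(1):
        raise ValueError(
            "no valid subclonal architecture under the pigeonhole constraints "
            f"(eps={eps}); cluster CCFs: {dict(zip(ids, ccf.tolist()))}"
        )
    assert _valid_tree(parents, ccf, eps)
    tree_parents = {ids[i]: (ids[parents[i]] if parents[i] >= 0 else None) for i in range(len(ids))}
    return CloneTree(
        parents=tree_parents,
        ccf=pd.DataFrame(ccf, index=ids, columns=list(clusters[0].ccf.index)),
        sizes={c.cluster_id: c.size for c in clusters},
    )


def enumerate_valid_trees(
    clusters: Sequence[MutationCluster] | np.ndarray,
    eps: float = 0.05,
    max_clusters: int = 6,
) -> set[tuple[int, ...]]:
    """All rooted trees satisfying the pigeonhole constraints (brute force).

    Accepts clusters or a raw (k x samples) CCF matrix; returns parent
    tuples indexed by cluster order with -1 marking the root. Guarded to
    small ``k`` — the enumeration is exponential.
    """
    if isinstance(clusters, np.ndarray):
        ccf = clusters
    else:
        ccf = np.vstack([c.ccf.to_numpy() for c in clusters])
    k = ccf.shape[0]
    if k > max_clusters:
        raise ValueError(f"enumeration guarded to <= {max_clusters} clusters")
    if k == 1:
        return {(-1,)}
    out: set[tuple[int, ...]] = set()
    nodes = list(range(k))
    for root in nodes:
        rest = [v for v in nodes if v != root]
        for choice in product(*[[u for u in nodes if u != v] for v in rest]):
            parents = np.full(k, -1, dtype=np.int64)
            for v, p in zip(rest, choice):
                parents[v] = p
            if _is_tree(parents, root) and _valid_tree(parents, ccf, eps):
                out.add(tuple(int(p) for p in parents))
    return out


def _is_tree(parents: np.ndarray, root: int) -> bool:
    k = len(parents)
    for v in range(k):
        seen = set()
        u = v
        while u != root:
            if u in seen:
                return False
            seen.add(u)
            u = parents[u]
            if u < 0 and u != parents[root]:
                return False
    return True


def build_phylogeny(tree: CloneTree, primary_total: int) -> CloneTree:
    """Scale branch lengths to the primary tumor's mutation count."""
    if primary_total <= 0:
        raise ValueError("primary_total must be positive")
    return CloneTree(parents=dict(tree.parents), ccf=tree.ccf.copy(), sizes=dict(tree.sizes), scale=primary_total)


# ---------------------------------------------------------------------------
# drivers


def label_drivers(
    case: PatientCase,
    clusters: Sequence[MutationCluster],
    categories: CategoryAssignment,
    driver_genes: Optional[Mapping[str, tuple]] = None,
) -> list[DriverAlteration]:
    """Map qualifying driver alterations onto the clonal structure.

    Qualifying alterations: (1) nonsynonymous SNVs/indels (and promoter
    mutations) in driver genes, timed by the category of their mutation
    cluster; (2) oncogene amplifications / TSG deletions, timed by the
    sample-presence pattern; (3) SV breakpoints inside driver genes, timed
    likewise. Silent driver-gene mutations never qualify.
    """
    driver_genes = driver_genes or DRIVER_GENES
    out: list[DriverAlteration] = []
    cat = categories.categories
    roles = {p.sample: p.role for p in case.profiles}

    def coarse(category: str) -> str:
        if category in ("trunk_clone", "trunk_subclone"):
            return category
        if category.endswith("_clone"):
            return "clone"
        if category.endswith("_subclone") and categories.scheme == "de_novo":
            return "subclone"
        return "branch"

    row_cluster: dict[int, str] = {}
    for c in clusters:
        for r in c.member_rows:
            row_cluster[int(r)] = c.cluster_id

    muts = case.mutations
    driver_rows = muts.index[
        muts["gene"].isin(driver_genes.keys())
        & muts["effect"].isin(["nonsynonymous", "promoter"])
    ]
    for r in driver_rows:
        gene = muts.at[r, "gene"]
        alteration = "promoter_mutation" if muts.at[r, "effect"] == "promoter" else "mutation"
        node = row_cluster.get(int(r))
        if node is None or node not in cat:
            warnings.warn(f"driver mutation in {gene} not in any retained cluster")
            out.append(DriverAlteration(gene=gene, alteration=alteration, node=None, timing="unplaced"))
        else:
            out.append(
                DriverAlteration(gene=gene, alteration=alteration, node=node, timing=coarse(cat[node]))
            )

    # CNV drivers per sample, then timed by presence pattern
    tumor_samples = case.tumor_samples
    cnv_hits: dict[tuple[str, str], list[str]] = {}
    for sample in tumor_samples:
        prof = case.profile(sample)
        seg = case.segments.get(sample)
        if seg is None or len(seg) == 0:
            continue
        for gene, (chrom, start, end, role) in driver_genes.items():
            mid = (start + end) // 2
            cn = local_copy_number_batch(seg, np.array([chrom], dtype=object), np.array([mid]), fallback=int(round(prof.ploidy)))[0]
            klass = classify_gene_cnv(int(cn), prof.ploidy)
            if role == "oncogene" and klass == "amplification":
                cnv_hits.setdefault((gene, "amplification"), []).append(sample)
            elif role == "TSG" and klass == "deletion":
                cnv_hits.setdefault((gene, "deletion"), []).append(sample)

    for (gene, alteration), samples in cnv_hits.items():
        out.append(
            DriverAlteration(
                gene=gene,
                alteration=alteration,
                node=None,
                timing=_presence_timing(samples, roles, categories.scheme),
                samples=tuple(samples),
            )
        )

    # SV breakpoints inside driver genes
    sv_hits: dict[str, list[str]] = {}
    for sample, bp in (case.breakpoints or {}).items():
        if roles.get(sample) == "normal" or len(bp) == 0:
            continue
        for gene, (chrom, start, end, _role) in driver_genes.items():
            in_gene = (
                ((bp["chrom1"].astype(str) == chrom) & bp["pos1"].between(start, end))
                | ((bp["chrom2"].astype(str) == chrom) & bp["pos2"].between(start, end))
            )
            if in_gene.any():
                sv_hits.setdefault(gene, []).append(sample)
    for gene, samples in sv_hits.items():
        out.append(
            DriverAlteration(
                gene=gene,
                alteration="sv_breakpoint",
                node=None,
                timing=_presence_timing(samples, roles, categories.scheme),
                samples=tuple(samples),
            )
        )
    return out


def _presence_timing(samples: Sequence[str], roles: Mapping[str, str], scheme: str) -> str:
    tumor = [s for s, r in roles.items() if r != "normal"]
    in_p = any(roles[s] == "primary" for s in samples)
    in_r = any(roles[s] == "recurrent" for s in samples)
    if scheme == "de_novo":
        return "clone" if set(samples) >= set(tumor) else "subclone"
    if in_p and in_r:
        return "trunk_clone" if set(samples) >= set(tumor) else "trunk_subclone"
    return "branch"


def driver_timing_summary(per_patient_drivers: Sequence[Sequence[DriverAlteration]]) -> pd.DataFrame:
    """Per-gene fractions of patients by timing class."""
    rows = []
    for i, drivers in enumerate(per_patient_drivers):
        seen = set()
        for d in drivers:
            key = (d.gene, d.alteration, d.timing)
            if key in seen:
                continue
            seen.add(key)
            rows.append({"patient": i, "gene": d.gene, "alteration": d.alteration, "timing": d.timing})
    if not rows:
        return pd.DataFrame(columns=["gene", "alteration", "timing", "n_patients", "fraction"])
    df = pd.DataFrame(rows)
    n_patients = df["patient"].nunique()
    summary = (
        df.groupby(["gene", "alteration", "timing"])["patient"]
        .nunique()
        .rename("n_patients")
        .reset_index()
    )
    summary["fraction"] = summary["n_patients"] / n_patients
    return summary


# ---------------------------------------------------------------------------
# heterogeneity and seeding


def pairwise_heterogeneity(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Intra-/inter-tumor heterogeneity as 1 - Jaccard of mutation sets."""
    return 1.0 - jaccard(set_a, set_b)


def spatial_temporal_ith(
    region_sets: Mapping[str, np.ndarray],
    roles: Mapping[str, str],
) -> HeterogeneityResult:
    """Spatial (within-tumor) vs temporal (cross-tumor) heterogeneity.

    Spatial pairs are region pairs within the primary tumor or within the
    recurrent tumor (pooled); temporal pairs cross the two tumors. Means are
    absent (None), not zero, when no qualifying pairs exist.
    """
    samples = [s for s in region_sets if roles.get(s) != "normal"]
    rows = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            kind = "spatial" if roles[a] == roles[b] else "temporal"
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "kind": kind,
                    "dissimilarity": pairwise_heterogeneity(region_sets[a], region_sets[b]),
                }
            )
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "kind", "dissimilarity"])
    spatial = df.loc[df["kind"] == "spatial", "dissimilarity"]
    temporal = df.loc[df["kind"] == "temporal", "dissimilarity"]
    return HeterogeneityResult(
        pairwise=df,
        spatial_mean=float(spatial.mean()) if len(spatial) else None,
        temporal_mean=float(temporal.mean()) if len(temporal) else None,
    )


def detect_polyclonal_seeding(
    clusters: Sequence[MutationCluster],
    categories: CategoryAssignment,
    roles: Mapping[str, str],
    presence_thr: float = 0.05,
    clonal_thr: float = 0.8,
) -> dict:
    """Polyclonal vs monoclonal seeding of a multi-region recurrence.

    Polyclonal iff at least two non-clonal trunk clusters are subclonally
    present (presence_thr <= CCF <= clonal_thr) in at least two recurrent
    regions. Clusters present in every recurrent region but absent from all
    primary regions are additionally flagged as monophyletic-dissemination
    candidates (a metastasis-founding lineage).
    """
    recurrent = [s for s, r in roles.items() if r == "recurrent"]
    primaries = [s for s, r in roles.items() if r == "primary"]
    if len(recurrent) < 2:
        raise ValueError("polyclonal seeding needs at least two recurrent regions")
    supporting = []
    ubiquitous = []
    for c in clusters:
        cat = categories.categories.get(c.cluster_id, "")
        sub_in_r = sum(presence_thr <= c.ccf[s] <= clonal_thr for s in recurrent)
        if cat == "trunk_subclone" and sub_in_r >= 2:
            supporting.append(c.cluster_id)
        in_all_r = all(c.ccf[s] >= presence_thr for s in recurrent)
        in_no_p = all(c.ccf[s] < presence_thr for s in primaries)
        if in_all_r and in_no_p:
            ubiquitous.append(c.cluster_id)
    return {
        "seeding": "polyclonal" if len(supporting) >= 2 else "monoclonal",
        "supporting_clusters": supporting,
        "recurrence_ubiquitous_clusters": ubiquitous,
    }
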