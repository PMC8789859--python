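"""Synthetic paired primary/recurrent tumor cohorts with known ground truth.

The generator emulates the statistical structure of a paired-biopsy
whole-genome study of liver-tumor early recurrence:

* two recurrence patterns — *ancestral* (one clone tree spans both tumors;
  25–80% of mutations shared) and *de novo* (two independent trees; <5%
  shared, the overlap coming from population hotspot coincidence);
* per-sample cancer cell fractions obeying the pigeonhole constraints
  (children of a clone never sum above it in any sample);
* Poisson sequencing depth (54x tumors / 36x normals) with binomial allele
  counts at the expected VAF implied by purity, local copy number and CCF;
* a background cohort catalog whose hotspot frequencies are long-tailed
  (Zipf) while most mutations are private singletons;
* copy-number-loss segments masking private mutations (exercising the CNV
  drop rule), low-CCF trunk subclones falling below caller thresholds in one
  sample (exercising force calling), silent-only decoy clusters (exercising
  the cluster filter), planted driver alterations, and trinucleotide
  contexts drawn from per-patient signature mixtures, including a
  T>A-dominant hypermutator state.

Every case is emitted together with a :class:`GroundTruth` from which the
pattern, clone tree, per-sample CCFs and cluster categories are re-derivable.
A ``noiseless`` mode (large fixed depth, rounded allele counts) makes the
truth exactly recoverable for oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import CohortCatalog, PatientCase, SampleProfile
from .io import write_mutation_frame
from . import signatures as sigs

# 22 autosome-like intervals totalling 2,800 Mb (hg19 proportions, scaled).
_RAW_MB = np.array(
    [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
     115, 107, 103, 90, 81, 78, 59, 63, 48, 51], dtype=float,
)
CHROM_LENGTHS = np.floor(_RAW_MB * (2800.0 / _RAW_MB.sum()) * 1e6).astype(np.int64)
CHROM_LENGTHS[-1] += int(2800e6 - CHROM_LENGTHS.sum())
CHROM_NAMES = [str(i) for i in range(1, 23)]
CHROM_OFFSETS = np.concatenate([[0], np.cumsum(CHROM_LENGTHS)])
GENOME_BP = int(CHROM_LENGTHS.sum())

_SNV_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]
_INDEL_PAIRS = [
    ("A", "-"), ("C", "-"), ("G", "-"), ("T", "-"),
    ("-", "A"), ("-", "C"), ("-", "G"), ("-", "T"),
]
ALLELE_PAIRS = _SNV_PAIRS + _INDEL_PAIRS

#: Liver-cancer driver genes with approximate genomic intervals and roles.
DRIVER_GENES = {
    "TP53": ("17", 7_565_097, 7_590_856, "TSG"),
    "AXIN1": ("16", 337_440, 402_673, "TSG"),
    "CTNNB1": ("3", 41_236_328, 41_301_587, "oncogene"),
    "ARID1A": ("1", 27_022_522, 27_108_601, "TSG"),
    "TERT": ("5", 1_253_287, 1_295_162, "oncogene"),
    "MYC": ("8", 128_748_315, 128_753_680, "oncogene"),
    "VEGFA": ("6", 43_737_946, 43_754_224, "oncogene"),
    "CCND1": ("11", 69_455_873, 69_469_242, "oncogene"),
    "FGF19": ("11", 69_513_000, 69_519_999, "oncogene"),
    "CDKN2A": ("9", 21_967_751, 21_995_300, "TSG"),
    "CDKN2B": ("9", 22_002_902, 22_009_312, "TSG"),
    "PTEN": ("10", 89_623_195, 89_728_532, "TSG"),
    "ATM": ("11", 108_093_559, 108_239_826, "TSG"),
    "TSC2": ("16", 2_097_990, 2_138_713, "TSG"),
    "IDH1": ("2", 209_100_951, 209_116_275, "oncogene"),
    "IDH2": ("15", 90_626_277, 90_645_736, "oncogene"),
    "ERBB2": ("17", 37_844_393, 37_884_915, "oncogene"),
    "ERBB3": ("12", 56_473_641, 56_497_291, "oncogene"),
    "BCL9": ("1", 147_013_182, 147_098_903, "oncogene"),
}


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults follow the cohort the package models: 22/40 ancestral patients,
    2–5 mutation clusters per tumor, 3,000–85,000 somatic mutations per tumor
    (right-skewed), 54x mean tumor depth, ancestral pairs sharing 25–80% of
    mutations, de novo pairs overlapping only through hotspot coincidence
    (<=0.5% of keys), a 200-tumor x 1,000-mutation background catalog with
    Zipf(1.5) hotspot frequencies, and a 12.5% hypermutator probability
    (burden > 9/Mb, T>A-dominant spectrum).
    """

    n_patients: int = 40
    ancestral_fraction: float = 22 / 40
    clusters_per_tumor: tuple[int, int] = (2, 5)
    mutations_per_tumor: tuple[int, int] = (3_000, 85_000)
    burden_log_mean: float = float(np.log(13_000.0))
    burden_log_sd: float = 0.8
    mean_depth: float = 54.0
    normal_depth: float = 36.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    shared_fraction_ancestral: tuple[float, float] = (0.25, 0.80)
    denovo_overlap_fraction: tuple[float, float] = (0.0, 0.005)
    catalog_tumors: int = 200
    catalog_muts_per_tumor: int = 1_000
    zipf_s: float = 1.5
    hotspot_fraction: float = 0.05
    hotspot_universe: int = 1_000_000
    hypermutator_prob: float = 0.125
    wgd_prob_primary: float = 0.2
    wgd_prob_recurrent_ancestral: float = 0.55
    wgd_prob_recurrent_denovo: float = 0.11
    # CI-eligible (nonsynonymous) rates; trunk enrichment mirrors the higher
    # nonsynonymous than genome-wide sharing seen in clonally related pairs.
    nonsyn_rate_trunk: float = 0.15
    nonsyn_rate_branch: float = 0.05
    silent_ratio: float = 0.4
    indel_fraction: float = 0.1
    hotspot_mutations_per_tumor: int = 20
    min_separation: float = 0.2
    trunk_s22: bool = False
    multi_region: bool = False
    n_regions: tuple[int, int] = (3, 3)
    polyclonal: bool = True
    noiseless: bool = False
    noiseless_depth: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.clusters_per_tumor,
            self.mutations_per_tumor,
            self.purity_range,
            self.shared_fraction_ancestral,
            self.denovo_overlap_fraction,
        ):
            if lo > hi:
                raise ValueError(f"invalid range ({lo}, {hi})")
        for p in (self.ancestral_fraction, self.hypermutator_prob, self.hotspot_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth for one patient case."""

    pattern: str  # "ancestral" | "de_novo"
    parents: dict[str, Optional[str]]
    cluster_ccfs: pd.DataFrame  # clusters x tumor samples
    cluster_category: dict[str, str]
    mut_cluster: np.ndarray  # per-mutation cluster label index, -1 = ambient
    cluster_ids: list[str]
    shared_fraction: float
    location: str
    hsi: int
    wgd: dict[str, bool]
    polyclonal: bool = False
    trunk_signature_mixture: Optional[dict[str, float]] = None
    branch_signature_mixture: Optional[dict[str, float]] = None
    planted_cnv_drop: Optional[np.ndarray] = None
    hypermutator: bool = False


# ---------------------------------------------------------------------------
# low-level samplers


_ZIPF_CDF_CACHE: dict[tuple[float, int], Optional[np.ndarray]] = {}


def zipf_draws(s: float, size: int, rng: np.random.Generator, universe: int = 1_000_000) -> np.ndarray:
    """Ranks drawn i.i.d. from a truncated Zipf(s) law, P(r) proportional to r^-s."""
    if s <= 1.0:
        raise ValueError("zipf exponent must exceed 1")
    key = (float(s), int(universe))
    if key not in _ZIPF_CDF_CACHE:
        ranks = np.arange(1, universe + 1, dtype=float)
        with np.errstate(under="ignore"):
            w = ranks ** (-float(s))
        total = w.sum()
        if total == 0 or not np.isfinite(total):  # s -> inf degenerate limit
            _ZIPF_CDF_CACHE[key] = None
        else:
            _ZIPF_CDF_CACHE[key] = np.cumsum(w) / total
    cdf = _ZIPF_CDF_CACHE[key]
    if cdf is None:
        return np.ones(size, dtype=np.int64)
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="left").astype(np.int64) + 1


def simulate_clone_tree(k_clusters: int, seed: int | np.random.Generator) -> np.ndarray:
    """Random rooted tree over ``k_clusters`` nodes as a parent array.

    Node 0 is the clonal root (parent -1); every other node attaches
    uniformly to a lower-numbered node, which guarantees a single root and
    acyclicity.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parents = np.full(k_clusters, -1, dtype=np.int64)
    for v in range(1, k_clusters):
        parents[v] = rng.integers(0, v)
    return parents


def assign_sample_ccfs(
    parents: np.ndarray,
    presence: np.ndarray,
    rng: np.random.Generator,
    min_separation: float = 0.2,
    subclonal_band: tuple[float, float] = (0.15, 0.75),
    max_tries: int = 800,
) -> np.ndarray:
    """Per-node per-sample CCFs by top-down stick breaking.

    ``presence`` is a boolean (node, sample) matrix stating in which samples
    each lineage exists; present roots get CCF 1. Each sibling group shares
    a Dirichlet split of a random fraction (< 1) of its parent's CCF, so
    sibling CCFs never sum above their parent in any sample by
    construction; configurations are re-drawn until cluster CCF vectors are
    pairwise separated by at least ``min_separation`` (L-inf over samples,
    progressively relaxed on crowded trees) and every present node clears
    the presence floor.
    """
    k, n_s = presence.shape
    # parent indices are always smaller than child indices in our layouts,
    # so index order is a topological order
    order = np.arange(k)
    lo0, hi = subclonal_band
    children = [np.flatnonzero(parents == v) for v in range(k)]
    for attempt in range(max_tries):
        # progressively relax separation and the presence floor rather than
        # fail outright on crowded trees
        sep = min_separation * 0.9 ** (attempt // 20)
        lo = max(0.04, lo0 * 0.85 ** (attempt // 40))
        ccf = np.zeros((k, n_s))
        ok = True
        for s in range(n_s):
            for v in order:
                if presence[v, s] and (parents[v] < 0 or not presence[parents[v], s]):
                    ccf[v, s] = 1.0
            for v in order:
                if not presence[v, s]:
                    continue
                kids = [c for c in children[v] if presence[c, s]]
                if not kids:
                    continue
                frac = rng.uniform(0.5, 0.95)
                shares = rng.dirichlet(np.full(len(kids), 2.0))
                alloc = np.minimum(ccf[v, s] * frac * shares, hi)
                ccf[kids, s] = alloc
                if (alloc < lo).any():
                    ok = False
            if not ok:
                break
        if not ok:
            continue
        d = np.abs(ccf[:, None, :] - ccf[None, :, :]).max(axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= sep:
            return ccf
    raise RuntimeError("could not satisfy CCF constraints; targets infeasible")


def simulate_reads(
    true_ccf: np.ndarray,
    purity: float,
    cn_mut: np.ndarray,
    depth_mean: float,
    rng: np.random.Generator,
    cn_norm: float = 2.0,
    noiseless: bool = False,
    noiseless_depth: int = 20_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequencing read counts at loci with the given true CCFs.

    Depth is Poisson(``depth_mean``); alt counts are Binomial at the expected
    VAF ``p*CCF / (cn_norm*(1-p) + p*cn_mut)`` (one mutated copy per cell).
    In noiseless mode depth is fixed and alt counts rounded.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    true_ccf = np.asarray(true_ccf, dtype=float)
    cn_mut = np.broadcast_to(np.asarray(cn_mut, dtype=float), true_ccf.shape)
    if np.any((cn_mut < 1) & (true_ccf > 0)):
        raise ValueError("cn_mut = 0 at a locus with true CCF > 0")
    denom = cn_norm * (1 - purity) + purity * np.maximum(cn_mut, 1.0)
    evaf = purity * true_ccf / denom
    if noiseless:
        depth = np.full(true_ccf.shape, noiseless_depth, dtype=np.int64)
        alt = np.rint(depth * evaf).astype(np.int64)
    else:
        depth = rng.poisson(depth_mean, size=true_ccf.shape).astype(np.int64)
        alt = rng.binomial(depth, np.clip(evaf, 0.0, 1.0))
    return alt, depth - alt


# ---------------------------------------------------------------------------
# key handling


def gpos_to_chrom_pos(gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gpos = np.asarray(gpos, dtype=np.int64)
    ci = np.searchsorted(CHROM_OFFSETS, gpos, side="right") - 1
    pos = gpos - CHROM_OFFSETS[ci] + 1
    chroms = np.asarray(CHROM_NAMES, dtype=object)[ci]
    return chroms, pos


def hotspot_key(rank: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (gpos, allele-code) for hotspot catalog ranks.

    Hotspot sites live at positions 1..universe on chromosome 1 with an
    allele pair fixed by the rank, so the same rank always denotes the same
    genomic mutation across patients and the catalog.
    """
    rank = np.asarray(rank, dtype=np.int64)
    gpos = rank  # chromosome 1, pos = rank
    code = (rank * 7919) % len(_SNV_PAIRS)
    return gpos, code


def keys_to_frame(gpos: np.ndarray, code: np.ndarray) -> pd.DataFrame:
    chroms, pos = gpos_to_chrom_pos(gpos)
    pairs = np.asarray(ALLELE_PAIRS, dtype=object)
    ref = pairs[code, 0]
    alt = pairs[code, 1]
    is_snv = code < len(_SNV_PAIRS)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "variant_class": np.where(is_snv, "SNV", "indel"),
        }
    )


# ---------------------------------------------------------------------------
# catalog


def simulate_catalog(
    n_tumors: int = 200,
    muts_per_tumor: int = 1_000,
    zipf_s: float = 1.5,
    seed: int | np.random.Generator = 0,
    hotspot_fraction: float = 0.05,
    universe: int = 1_000_000,
) -> tuple[CohortCatalog, list[np.ndarray], pd.DataFrame]:
    """Background cohort: per-tumor mutation sets plus the aggregated catalog.

    Each tumor's set mixes a small hotspot fraction of Zipf(``zipf_s``)
    draws (recurrently mutated sites shared across the cohort) with private
    uniform-genome mutations, so aggregated hotspot frequencies are
    long-tailed while most catalog entries are singletons — the structure
    that makes a chance-co-occurrence clonality index informative.

    Returns ``(catalog, per_tumor_keys, key_table)`` where ``per_tumor_keys``
    are sorted int64 key ids and ``key_table`` maps key ids to
    (chrom, pos, ref, alt) rows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hot = int(round(hotspot_fraction * muts_per_tumor))
    sets: list[np.ndarray] = []
    for _ in range(n_tumors):
        ranks = np.unique(zipf_draws(zipf_s, n_hot, rng, universe)) if n_hot else np.array([], dtype=np.int64)
        gpos_h, code_h = hotspot_key(ranks)
        keys_h = gpos_h * 32 + code_h
        n_priv = muts_per_tumor - len(keys_h)
        gpos_p = rng.integers(universe + 1, GENOME_BP, size=n_priv, dtype=np.int64)
        code_p = rng.integers(0, len(_SNV_PAIRS), size=n_priv, dtype=np.int64)
        keys_p = gpos_p * 32 + code_p
        sets.append(np.unique(np.concatenate([keys_h, keys_p])))
    all_keys = np.concatenate(sets)
    uniq, counts = np.unique(all_keys, return_counts=True)
    frame = keys_to_frame(uniq >> 5, uniq & 31)
    frame["key_id"] = uniq
    frame["count"] = counts
    catalog = CohortCatalog(
        counts={
            (r.chrom, int(r.pos), r.ref, r.alt): int(r.count)
            for r in frame.itertuples(index=False)
        },
        n_total=int(counts.sum()),
        n_tumors=n_tumors,
    )
    return catalog, sets, frame


# ---------------------------------------------------------------------------
# per-case simulation


def _tree_layout(pattern: str, params: SimulationParams, rng: np.random.Generator):
    """Cluster ids, parent links, structural labels and presence matrix.

    Samples are ordered primary regions first, then recurrent regions.
    """
    if params.multi_region:
        n_p, n_r = params.n_regions
    else:
        n_p, n_r = 1, 1
    n_s = n_p + n_r
    if pattern == "ancestral":
        # polyclonal seeding needs >= 2 trunk subclones subclonally present
        # across recurrent regions
        n_ts = 2 if (params.multi_region and params.polyclonal) else int(rng.integers(1, 3))
        n_pb = int(rng.integers(1, 3))
        n_rb = int(rng.integers(1, 3))
        labels = (
            ["trunk_clone"]
            + ["trunk_subclone"] * n_ts
            + ["primary_branch"] * n_pb
            + ["recurrence_branch"] * n_rb
        )
        parents = [-1]
        for i in range(n_ts):  # chain or fan under the root
            parents.append(0 if (i == 0 or rng.random() < 0.5) else i)
        trunk_nodes = list(range(0, 1 + n_ts))
        for _ in range(n_pb):
            parents.append(int(rng.choice(trunk_nodes)))
        subclone_nodes = trunk_nodes[1:]
        for _ in range(n_rb):
            parents.append(int(rng.choice(subclone_nodes)))
        k = len(parents)
        presence = np.zeros((k, n_s), dtype=bool)
        for v, lab in enumerate(labels):
            if lab in ("trunk_clone", "trunk_subclone"):
                presence[v, :] = True
            elif lab == "primary_branch":
                # multi-region: branch clusters span their tumor's regions;
                # regional variation is carried by the small leaf clusters,
                # keeping within-tumor divergence below the cross-tumor
                # divergence as in the emulated study design
                presence[v, :n_p] = True if params.multi_region else _region_subset(n_p, rng)
            else:
                presence[v, n_p:] = True if params.multi_region else _region_subset(n_r, rng)
        if params.multi_region:
            # a recurrence-ubiquitous cluster (metastasis-founding candidate)
            presence[len(labels) - 1, n_p:] = True
            if params.polyclonal and n_ts >= 1:
                # >=2 non-clonal trunk clusters subclonal in >=2 recurrent regions
                for v in range(1, 1 + n_ts):
                    presence[v, n_p:] = True
            # leaf clusters private to single regions
            for region in range(min(2, n_s)):
                labels.append("leaf_subclone")
                parents.append(0)
                row = np.zeros(n_s, dtype=bool)
                row[region] = True
                presence = np.vstack([presence, row])
    elif pattern == "de_novo":
        k_max = min(4, params.clusters_per_tumor[1])
        k_p = int(rng.integers(2, k_max + 1))
        k_r = int(rng.integers(2, k_max + 1))
        labels = (
            ["primary_clone"] + ["primary_subclone"] * (k_p - 1)
            + ["recurrence_clone"] + ["recurrence_subclone"] * (k_r - 1)
        )
        parents = [-1] + [int(rng.integers(0, v)) for v in range(1, k_p)]
        parents += [-1] + [int(k_p + rng.integers(0, v)) for v in range(1, k_r)]
        k = len(parents)
        presence = np.zeros((k, n_s), dtype=bool)
        presence[:k_p, :n_p] = True
        presence[k_p:, n_p:] = True
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return labels, np.asarray(parents), presence, n_p, n_r


def _region_subset(n: int, rng: np.random.Generator) -> np.ndarray:
    """Nonempty random subset of regions (contiguous prefix after shuffle)."""
    m = int(rng.integers(1, n + 1))
    out = np.zeros(n, dtype=bool)
    out[rng.permutation(n)[:m]] = True
    return out


def _assign_denovo_ccfs(parents, presence, labels, params, rng):
    """Stick-breaking per tumor-specific tree; absent samples get CCF 0."""
    k, n_s = presence.shape
    ccf = np.zeros((k, n_s))
    roots = [v for v in range(k) if parents[v] < 0]
    for root in roots:
        nodes = [v for v in range(k) if _tree_root(parents, v) == root]
        sub_parents = np.array([parents[v] if v != root else -1 for v in nodes])
        remap = {v: i for i, v in enumerate(nodes)}
        sub_parents = np.array([remap[parents[v]] if v != root else -1 for v in nodes])
        sub_presence = presence[nodes]
        sub = assign_sample_ccfs(sub_parents, sub_presence, rng, params.min_separation)
        ccf[nodes] = sub
    return ccf


def _tree_root(parents, v):
    while parents[v] >= 0:
        v = parents[v]
    return v


def _cluster_sizes(pattern, labels, shared_target, burden, rng):
    """Mutation counts per cluster hitting the shared-fraction target.

    For ancestral cases the trunk carries ``f_p`` of the primary burden and
    ``f_r`` of the recurrent burden with mean equal to the target; the trunk
    clone receives a minority of the trunk mass (clonally related recurrences
    accumulate most shared mutations while still subclonal).
    """
    k = len(labels)
    sizes = np.zeros(k, dtype=np.int64)
    if pattern == "ancestral":
        delta = rng.uniform(0.0, min(0.06, shared_target - 0.1, 0.92 - shared_target))
        f_p = shared_target + delta
        f_r = shared_target - delta
        trunk = max(2, int(round(f_p * burden)))
        n_primary_branch = burden - trunk
        recurrent_total = int(round(trunk / f_r))
        n_recur_branch = max(0, recurrent_total - trunk)
        trunk_nodes = [i for i, l in enumerate(labels) if l in ("trunk_clone", "trunk_subclone")]
        root_share = rng.uniform(0.15, 0.35)
        sizes[0] = max(1, int(root_share * trunk))
        _split(sizes, trunk_nodes[1:], trunk - sizes[0], rng)
        _split(sizes, [i for i, l in enumerate(labels) if l == "primary_branch"], n_primary_branch, rng)
        rb = [i for i, l in enumerate(labels) if l == "recurrence_branch"]
        leaf = [i for i, l in enumerate(labels) if l == "leaf_subclone"]
        leaf_mass = int(0.02 * burden) * len(leaf)
        _split(sizes, rb, max(len(rb), n_recur_branch - leaf_mass), rng)
        _split(sizes, leaf, leaf_mass, rng)
    else:
        raise ValueError("only ancestral cases size clusters through this helper")
    return sizes


def _split(sizes, nodes, total, rng):
    if not nodes or total <= 0:
        return
    w = rng.dirichlet(np.full(len(nodes), 4.0))
    alloc = np.maximum(1, np.rint(w * total).astype(np.int64))
    sizes[np.asarray(nodes)] = alloc


def _split_clone(sizes, nodes, total, rng):
    w = rng.dirichlet(np.full(len(nodes), 4.0))
    alloc = np.maximum(1, np.rint(w * total).astype(np.int64))
    sizes[np.asarray(nodes)] = alloc


def simulate_case(
    pattern: str,
    params: SimulationParams,
    seed: int | np.random.Generator,
    patient_id: str = "P1",
    signature_matrix: Optional[pd.DataFrame] = None,
) -> tuple[PatientCase, GroundTruth]:
    """One synthetic patient: mutation table, read support, segments, truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = signature_matrix if signature_matrix is not None else sigs.synthetic_reference_signatures()

    hyper = bool(rng.random() < params.hypermutator_prob)
    lo, hi = params.mutations_per_tumor
    if hyper:
        burden = int(np.clip(rng.lognormal(np.log(40_000), 0.4), max(lo, 26_000), hi))
    else:
        burden = int(np.clip(rng.lognormal(params.burden_log_mean, params.burden_log_sd), lo, hi))

    labels, parents, presence, n_p, n_r = _tree_layout(pattern, params, rng)
    k = len(labels)
    cluster_ids = [f"C{i}" for i in range(k)]
    if pattern == "ancestral":
        shared_target = rng.uniform(*params.shared_fraction_ancestral)
        ccf = assign_sample_ccfs(parents, presence, rng, params.min_separation)
        sizes = _cluster_sizes(pattern, labels, shared_target, burden, rng)
    else:
        shared_target = 0.0
        ccf = _assign_denovo_ccfs(parents, presence, labels, params, rng)
        burden_r = int(np.clip(rng.lognormal(params.burden_log_mean, params.burden_log_sd), lo, hi))
        sizes = np.zeros(k, dtype=np.int64)
        p_nodes = [i for i, l in enumerate(labels) if l.startswith("primary")]
        r_nodes = [i for i, l in enumerate(labels) if l.startswith("recurrence")]
        _split_clone(sizes, p_nodes, burden, rng)
        _split_clone(sizes, r_nodes, burden_r, rng)

    # --- mutation keys per cluster -------------------------------------
    n_mut = int(sizes.sum())
    cluster_of = np.repeat(np.arange(k), sizes)
    gpos = rng.integers(params.hotspot_universe + 1, GENOME_BP, size=n_mut, dtype=np.int64)
    code = np.where(
        rng.random(n_mut) < params.indel_fraction,
        len(_SNV_PAIRS) + rng.integers(0, len(_INDEL_PAIRS), size=n_mut),
        rng.integers(0, len(_SNV_PAIRS), size=n_mut),
    )

    # population hotspots: recurrent coding sites drawn from the Zipf head,
    # placed on the clonal cluster of each tumor
    hot_targets = [0] if pattern == "ancestral" else [
        next(i for i, l in enumerate(labels) if l == "primary_clone"),
        next(i for i, l in enumerate(labels) if l == "recurrence_clone"),
    ]
    hot_cluster, hot_gpos, hot_code = [], [], []
    for node in hot_targets:
        ranks = np.unique(zipf_draws(params.zipf_s, params.hotspot_mutations_per_tumor, rng, params.hotspot_universe))
        g, c = hotspot_key(ranks)
        hot_cluster.append(np.full(len(ranks), node))
        hot_gpos.append(g)
        hot_code.append(c)

    # de novo: small planted overlap via shared hotspot keys on subclones
    ambient_cluster, ambient_gpos, ambient_code = [], [], []
    if pattern == "de_novo":
        frac = rng.uniform(*params.denovo_overlap_fraction)
        n_overlap = int(frac * burden)
        if n_overlap:
            ranks = np.unique(zipf_draws(params.zipf_s, n_overlap, rng, params.hotspot_universe))
            g, c = hotspot_key(ranks)
            ambient_gpos.append(g)
            ambient_code.append(c)
            ambient_cluster.append(np.full(len(ranks), -1))

    n_base = len(gpos)
    n_hot = sum(len(g) for g in hot_gpos)
    n_amb = sum(len(g) for g in ambient_gpos)
    gpos = np.concatenate([gpos] + hot_gpos + ambient_gpos)
    code = np.concatenate([code] + hot_code + ambient_code).astype(np.int64)
    cluster_of = np.concatenate([cluster_of] + hot_cluster + ambient_cluster).astype(np.int64)
    # hotspot draws on the clonal clusters are recurrent coding sites; the
    # planted de novo overlap keys are NOT forced coding (independent pairs
    # share mostly passenger coincidence, keeping their clonality index low)
    forced_nonsyn = np.concatenate(
        [np.zeros(n_base, bool), np.ones(n_hot, bool), np.zeros(n_amb, bool)]
    )

    # dedupe on key
    key_int = gpos * 32 + code
    _, first = np.unique(key_int, return_index=True)
    keep = np.sort(first)
    gpos, code, cluster_of, forced_nonsyn = (
        gpos[keep], code[keep], cluster_of[keep], forced_nonsyn[keep],
    )
    n_mut = len(gpos)
    order = np.argsort(gpos * 32 + code, kind="stable")
    gpos, code, cluster_of, forced_nonsyn = (
        gpos[order], code[order], cluster_of[order], forced_nonsyn[order],
    )

    samples = [f"{patient_id}_T{i+1}" for i in range(n_p)] + [f"{patient_id}_R{i+1}" for i in range(n_r)]
    roles = ["primary"] * n_p + ["recurrent"] * n_r

    # --- per-mutation CCF matrix over tumor samples ---------------------
    mut_ccf = np.zeros((n_mut, n_p + n_r))
    in_tree = cluster_of >= 0
    mut_ccf[in_tree] = ccf[cluster_of[in_tree]]
    if pattern == "de_novo" and (~in_tree).any():
        # ambient overlap keys sit on a random subclone of each tree
        p_sub = [i for i, l in enumerate(labels) if l == "primary_subclone"]
        r_sub = [i for i, l in enumerate(labels) if l == "recurrence_subclone"]
        src_p = int(rng.choice(p_sub)) if p_sub else 0
        src_r = int(rng.choice(r_sub)) if r_sub else k - 1
        mut_ccf[~in_tree, :n_p] = ccf[src_p, :n_p]
        mut_ccf[~in_tree, n_p:] = ccf[src_r, n_p:]

    # --- effects: trunk-enriched nonsynonymous rates --------------------
    trunk_like = np.zeros(n_mut, dtype=bool)
    shared_labels = ("trunk_clone", "trunk_subclone", "primary_clone", "recurrence_clone")
    trunk_like[in_tree] = np.isin(np.asarray(labels, dtype=object)[cluster_of[in_tree]], shared_labels)
    p_nonsyn = np.where(trunk_like, params.nonsyn_rate_trunk, params.nonsyn_rate_branch)
    u = rng.random(n_mut)
    effect = np.full(n_mut, "noncoding", dtype=object)
    effect[u < p_nonsyn] = "nonsynonymous"
    sil = (u >= p_nonsyn) & (u < p_nonsyn * (1 + params.silent_ratio))
    effect[sil] = "silent"
    spl = (u >= 0.99) & (u < 0.995)
    effect[spl] = "splice"
    effect[u >= 0.995] = "promoter"
    effect[forced_nonsyn] = "nonsynonymous"

    # --- silent-only decoy cluster (exercises the cluster filter) -------
    n_decoy = max(10, int(0.002 * burden))
    decoy_gpos = rng.integers(params.hotspot_universe + 1, GENOME_BP, size=n_decoy, dtype=np.int64)
    decoy_code = rng.integers(0, len(_SNV_PAIRS), size=n_decoy, dtype=np.int64)
    decoy_ccf_vec = np.zeros(n_p + n_r)
    decoy_ccf_vec[:n_p] = 0.999  # rides with the primary clone, silent only
    gpos = np.concatenate([gpos, decoy_gpos])
    code = np.concatenate([code, decoy_code])
    cluster_of = np.concatenate([cluster_of, np.full(n_decoy, -2)])
    mut_ccf = np.vstack([mut_ccf, np.tile(decoy_ccf_vec, (n_decoy, 1))])
    effect = np.concatenate([effect, np.full(n_decoy, "silent", dtype=object)])
    n_mut = len(gpos)

    # --- driver planting -------------------------------------------------
    genes = np.full(n_mut, "", dtype=object)
    driver_rows = []
    trunk_nodes = [i for i, l in enumerate(labels) if l in ("trunk_clone", "trunk_subclone", "primary_clone", "recurrence_clone")]
    driver_picks = rng.choice(["TP53", "AXIN1", "CTNNB1", "ARID1A", "TERT"], size=2, replace=False)
    for gene in driver_picks:
        chrom, start, end, _role = DRIVER_GENES[gene]
        ci = CHROM_NAMES.index(chrom)
        g = CHROM_OFFSETS[ci] + int(rng.integers(start, end))
        node = int(rng.choice(trunk_nodes))
        driver_rows.append((g, int(rng.integers(0, len(_SNV_PAIRS))), node, gene))
    for g, c, node, gene in driver_rows:
        gpos = np.append(gpos, g)
        code = np.append(code, c)
        cluster_of = np.append(cluster_of, node)
        mut_ccf = np.vstack([mut_ccf, ccf[node][None, :]])
        eff = "promoter" if gene == "TERT" else "nonsynonymous"
        effect = np.append(effect, eff)
        genes = np.append(genes, gene)
    n_mut = len(gpos)

    # --- CNV segments ----------------------------------------------------
    purity = rng.uniform(*params.purity_range, size=n_p + n_r)
    wgd = {}
    ploidy = np.zeros(n_p + n_r)
    for j, role in enumerate(roles):
        if role == "primary":
            p_wgd = params.wgd_prob_primary
        else:
            p_wgd = (
                params.wgd_prob_recurrent_ancestral
                if pattern == "ancestral"
                else params.wgd_prob_recurrent_denovo
            )
        flag = bool(rng.random() < p_wgd)
        wgd[samples[j]] = flag
        ploidy[j] = rng.uniform(3.0, 3.8) if flag else rng.uniform(1.8, 2.4)
    base_cn = np.rint(ploidy).astype(int)

    seg_rows = []
    for j, sample in enumerate(samples):
        for ci, name in enumerate(CHROM_NAMES):
            seg_rows.append({"sample": sample, "chrom": name, "start": 1,
                             "end": int(CHROM_LENGTHS[ci]), "total_cn": int(base_cn[j])})
    segments = pd.DataFrame(seg_rows)

    # CNV-loss window in the first recurrent sample over a slice of
    # primary-private mutations (these get excluded by the CNV drop rule)
    planted_drop = np.zeros(n_mut, dtype=bool)
    private_primary = (mut_ccf[:, :n_p].max(axis=1) > 0) & (mut_ccf[:, n_p:].max(axis=1) == 0)
    cand = np.flatnonzero(private_primary)
    if len(cand) >= 10:
        picked = cand[rng.permutation(len(cand))[: max(5, int(0.003 * n_mut))]]
        win_lo, win_hi = 200_000_000, 210_000_000  # window on chromosome 1
        # evenly spaced relocated positions: unique keys guaranteed
        gpos[picked] = win_lo + np.arange(len(picked), dtype=np.int64) * 1_000 + 17
        planted_drop[picked] = True
        loss_sample = samples[n_p]  # first recurrent region
        segments = _overlay_segment(segments, loss_sample, win_lo, win_hi, 1)

    # driver CNV events: oncogene amplification / TSG deletion
    cnv_driver_genes = rng.choice(["MYC", "VEGFA", "CCND1", "CDKN2A", "PTEN", "ERBB2"], size=2, replace=False)
    for gene in cnv_driver_genes:
        chrom, start, end, role = DRIVER_GENES[gene]
        ci = CHROM_NAMES.index(chrom)
        glo = CHROM_OFFSETS[ci] + start - 50_000
        ghi = CHROM_OFFSETS[ci] + end + 50_000
        targets = range(n_p, n_p + n_r) if rng.random() < 0.5 else range(n_p + n_r)
        for j in targets:
            cn = 0 if role == "TSG" else int(np.ceil(2 * ploidy[j])) + 1
            segments = _overlay_segment(segments, samples[j], glo, ghi, cn)

    # --- contexts from the per-patient signature mixture -----------------
    sig_names = list(S.columns)
    if hyper:
        trunk_mix = {"Signature.22": 0.75, "Signature.5": 0.25}
        branch_mix = dict(trunk_mix)
    else:
        picks = rng.choice(["Signature.1", "Signature.4", "Signature.5", "Signature.12",
                            "Signature.16", "Signature.24"], size=3, replace=False)
        w = rng.dirichlet(np.ones(3))
        trunk_mix = {g: float(x) for g, x in zip(picks, w)}
        branch_mix = dict(trunk_mix)
        if params.trunk_s22:
            trunk_mix = {g: 0.5 * x for g, x in trunk_mix.items()}
            trunk_mix["Signature.22"] = 0.5
    ref_arr, alt_arr, ctx_arr = _alleles_and_contexts(
        gpos, code, trunk_like_full(trunk_like, n_mut), trunk_mix, branch_mix, S, rng, params.hotspot_universe
    )

    # --- read simulation --------------------------------------------------
    chroms, pos = gpos_to_chrom_pos(gpos)
    alt_mat = np.zeros((n_mut, n_p + n_r + 1), dtype=np.int64)
    ref_mat = np.zeros((n_mut, n_p + n_r + 1), dtype=np.int64)
    called = np.zeros((n_mut, n_p + n_r + 1), dtype=bool)
    from .io import local_copy_number_batch  # local import to avoid cycle

    normal_depth = (
        np.full(n_mut, params.noiseless_depth, dtype=np.int64)
        if params.noiseless
        else rng.poisson(params.normal_depth, size=n_mut).astype(np.int64)
    )
    for j, sample in enumerate(samples):
        seg_j = segments[segments["sample"] == sample]
        cn = local_copy_number_batch(seg_j, chroms, pos, fallback=base_cn[j])
        cn_eff = np.maximum(cn, 1)  # deleted loci cannot carry the variant
        ccf_here = np.where(cn == 0, 0.0, mut_ccf[:, j])
        a, r = simulate_reads(
            ccf_here, purity[j], cn_eff, params.mean_depth, rng,
            noiseless=params.noiseless, noiseless_depth=params.noiseless_depth,
        )
        alt_mat[:, j] = a
        ref_mat[:, j] = r
        depth = a + r
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, a / np.maximum(depth, 1), 0.0)
        called[:, j] = (
            (mut_ccf[:, j] > 0) & (depth >= 10) & (a >= 3) & (vaf >= 0.05) & (normal_depth >= 10)
        )
    alt_mat[:, -1] = 0
    ref_mat[:, -1] = normal_depth

    mutations = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref_arr,
            "alt": alt_arr,
            "variant_class": np.where(code < len(_SNV_PAIRS), "SNV", "indel"),
            "gene": genes,
            "effect": effect,
            "context": ctx_arr,
        }
    )

    # --- location / profiles ---------------------------------------------
    if pattern == "ancestral":
        local = rng.random() < 20 / 22
    else:
        local = rng.random() < 8 / 18
    seg_primary = {int(rng.integers(1, 9))}
    if local:
        shift = int(rng.integers(0, 2))
    else:
        shift = int(rng.integers(2, 5))
    base_seg = next(iter(seg_primary))
    seg_recurrent = {int(np.clip(base_seg + shift if base_seg + shift <= 8 else base_seg - shift, 1, 8))}
    hsi = min(abs(a - b) for a in seg_primary for b in seg_recurrent)

    profiles = [
        SampleProfile(
            sample=samples[j],
            patient=patient_id,
            role=roles[j],
            purity=float(purity[j]),
            ploidy=float(ploidy[j]),
            region=f"{'T' if roles[j] == 'primary' else 'R'}{(j % max(n_p, 1)) + 1}",
            hepatic_segments=frozenset(seg_primary if roles[j] == "primary" else seg_recurrent),
        )
        for j in range(n_p + n_r)
    ] + [SampleProfile(sample=f"{patient_id}_N", patient=patient_id, role="normal")]

    # --- breakpoints -------------------------------------------------------
    breakpoints = _simulate_breakpoints(pattern, samples, n_p, rng)

    case = PatientCase(
        patient=patient_id,
        profiles=profiles,
        mutations=mutations,
        alt_reads=alt_mat,
        ref_reads=ref_mat,
        called=called,
        segments={s: g.reset_index(drop=True) for s, g in segments.groupby("sample")},
        breakpoints=breakpoints,
        recurrence_months=float(rng.uniform(3, 24)),
    )

    if params.multi_region:
        # multi-region categories follow presence patterns, not the
        # structural role the cluster was built with
        category = {}
        for i in range(k):
            if labels[i] == "trunk_clone":
                category[cluster_ids[i]] = "trunk_clone"
            elif presence[i].all():
                category[cluster_ids[i]] = "trunk_subclone"
            elif presence[i].sum() > 1:
                category[cluster_ids[i]] = "branch_subclone"
            else:
                category[cluster_ids[i]] = "leaf_subclone"
    else:
        category = {cluster_ids[i]: labels[i] for i in range(k)}
    truth = GroundTruth(
        pattern=pattern,
        parents={cluster_ids[i]: (cluster_ids[parents[i]] if parents[i] >= 0 else None) for i in range(k)},
        cluster_ccfs=pd.DataFrame(ccf, index=cluster_ids, columns=samples),
        cluster_category=category,
        mut_cluster=cluster_of,
        cluster_ids=cluster_ids,
        shared_fraction=shared_target,
        location="local" if hsi <= 1 else "distant",
        hsi=int(hsi),
        wgd=wgd,
        polyclonal=bool(params.multi_region and params.polyclonal and pattern == "ancestral"),
        trunk_signature_mixture=trunk_mix,
        branch_signature_mixture=branch_mix,
        planted_cnv_drop=planted_drop,
        hypermutator=hyper,
    )
    return case, truth


def trunk_like_full(trunk_like: np.ndarray, n_mut: int) -> np.ndarray:
    out = np.zeros(n_mut, dtype=bool)
    out[: len(trunk_like)] = trunk_like
    out[len(trunk_like):] = True  # planted drivers ride trunk nodes
    return out


def _overlay_segment(segments: pd.DataFrame, sample: str, glo: int, ghi: int, cn: int) -> pd.DataFrame:
    """Punch a [glo, ghi) global-coordinate window at copy number ``cn``."""
    chroms, lo_pos = gpos_to_chrom_pos(np.array([glo]))
    _, hi_pos = gpos_to_chrom_pos(np.array([ghi - 1]))
    chrom = chroms[0]
    lo, hi = int(lo_pos[0]), int(hi_pos[0])
    rows = []
    for r in segments.itertuples(index=False):
        if r.sample != sample or r.chrom != chrom or r.end < lo or r.start > hi:
            rows.append(r._asdict())
            continue
        if r.start < lo:
            rows.append({**r._asdict(), "end": lo - 1})
        rows.append({"sample": sample, "chrom": chrom, "start": max(r.start, lo),
                     "end": min(r.end, hi), "total_cn": cn})
        if r.end > hi:
            rows.append({**r._asdict(), "start": hi + 1})
    return pd.DataFrame(rows)


def _alleles_and_contexts(gpos, code, trunk_like, trunk_mix, branch_mix, S, rng, universe):
    """Sample ref/alt/context per SNV from the patient's signature mixtures.

    Hotspot sites keep their deterministic alleles (a site's alleles cannot
    vary between patients); ~30% of SNVs are emitted on the purine strand to
    exercise the reverse-complement convention downstream.
    """
    n = len(gpos)
    pairs = np.asarray(ALLELE_PAIRS, dtype=object)
    ref = pairs[code, 0].copy()
    alt = pairs[code, 1].copy()
    ctx = np.full(n, "", dtype=object)
    is_snv = code < len(_SNV_PAIRS)
    is_hot = gpos <= universe

    def mixture_probs(mix):
        w = np.zeros(S.shape[1])
        for name, x in mix.items():
            w[S.columns.get_loc(name)] = x
        q = S.to_numpy() @ (w / max(w.sum(), 1e-12))
        return q / q.sum()

    q_trunk = mixture_probs(trunk_mix)
    q_branch = mixture_probs(branch_mix)
    for mask, q in (((is_snv & ~is_hot) & trunk_like, q_trunk), ((is_snv & ~is_hot) & ~trunk_like, q_branch)):
        m = int(mask.sum())
        if m == 0:
            continue
        cats = rng.choice(96, size=m, p=q)
        r, a, c = sigs.category_to_alleles(cats)
        flip = rng.random(m) < 0.3
        r[flip], a[flip], c[flip] = (
            sigs.complement_alleles(r[flip]),
            sigs.complement_alleles(a[flip]),
            sigs.reverse_complement_contexts(c[flip]),
        )
        ref[mask], alt[mask], ctx[mask] = r, a, c
    # hotspot SNVs: deterministic context from the site's alleles
    hot_snv = is_snv & is_hot
    if hot_snv.any():
        ctx[hot_snv] = np.array(
            ["ACA"[:1] + r + "A" for r in ref[hot_snv]], dtype=object
        )
    return ref, alt, ctx


def _simulate_breakpoints(pattern, samples, n_p, rng):
    """Structural-variant and viral-integration breakpoint tables.

    Ancestral pairs share some breakpoints between tumors; de novo pairs
    never do.
    """
    rows = {s: [] for s in samples}

    def random_bp(kind):
        g1 = int(rng.integers(1, GENOME_BP))
        g2 = int(rng.integers(1, GENOME_BP))
        c1, p1 = gpos_to_chrom_pos(np.array([g1]))
        c2, p2 = gpos_to_chrom_pos(np.array([g2]))
        return {"type": kind, "chrom1": c1[0], "pos1": int(p1[0]), "chrom2": c2[0], "pos2": int(p2[0])}

    shared_sv = [random_bp("SV") for _ in range(int(rng.integers(2, 8)))] if pattern == "ancestral" else []
    shared_hbv = [random_bp("HBV") for _ in range(int(rng.integers(1, 3)))] if pattern == "ancestral" else []
    for j, s in enumerate(samples):
        if pattern == "ancestral":
            rows[s].extend(shared_sv)
            rows[s].extend(shared_hbv)
        for _ in range(int(rng.integers(0, 6))):
            rows[s].append(random_bp("SV"))
    out = {}
    for s in samples:
        df = pd.DataFrame(rows[s], columns=["type", "chrom1", "pos1", "chrom2", "pos2"])
        df.insert(0, "sample", s)
        out[s] = df
    return out


# ---------------------------------------------------------------------------
# cohort level


def simulate_cohort(params: SimulationParams, seed: Optional[int] = None):
    """Full cohort: cases with truth, plus the background catalog.

    Returns ``(cases, truths, catalog, per_tumor_sets)``.
    """
    base_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    catalog, sets, _frame = simulate_catalog(
        params.catalog_tumors,
        params.catalog_muts_per_tumor,
        params.zipf_s,
        rng,
        params.hotspot_fraction,
        params.hotspot_universe,
    )
    n_anc = int(round(params.ancestral_fraction * params.n_patients))
    patterns = ["ancestral"] * n_anc + ["de_novo"] * (params.n_patients - n_anc)
    perm = rng.permutation(params.n_patients)
    cases, truths = [], []
    S = sigs.synthetic_reference_signatures()
    for i, idx in enumerate(perm):
        case, truth = simulate_case(
            patterns[idx], params, rng, patient_id=f"P{i+1:02d}", signature_matrix=S
        )
        cases.append(case)
        truths.append(truth)
    return cases, truths, catalog, sets


def write_case_files(case: PatientCase, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Emit a case as the on-disk formats the pipeline consumes.

    Writes ``mutations.tsv``, ``segments.tsv``, ``breakpoints.tsv``,
    ``manifest.yaml`` and ``truth.json``; returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    keys = case.mutations
    frames = []
    depth = case.depth()
    for j, sample in enumerate(case.samples):
        has = depth[:, j] > 0
        sub = keys.loc[has].copy()
        sub["sample"] = sample
        sub["alt_reads"] = case.alt_reads[has, j]
        sub["ref_reads"] = case.ref_reads[has, j]
        sub["called"] = case.called[has, j]
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    write_mutation_frame(long, out / "mutations.tsv")
    seg = pd.concat(case.segments.values(), ignore_index=True)
    seg[["sample", "chrom", "start", "end", "total_cn"]].to_csv(out / "segments.tsv", sep="\t", index=False)
    if case.breakpoints:
        bp = pd.concat(case.breakpoints.values(), ignore_index=True)
        bp.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
    manifest = {
        "patient": case.patient,
        "recurrence_months": case.recurrence_months,
        "mutation_table": "mutations.tsv",
        "cnv_segments": "segments.tsv",
        "breakpoints": "breakpoints.tsv" if case.breakpoints else None,
        "samples": [
            {
                "id": p.sample,
                "role": p.role,
                "region": p.region,
                "purity": p.purity,
                "ploidy": p.ploidy,
                "hepatic_segments": sorted(p.hepatic_segments),
            }
            for p in case.profiles
        ],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    import json

    truth_doc = {
        "pattern": truth.pattern,
        "parents": truth.parents,
        "cluster_ccfs": truth.cluster_ccfs.to_dict(),
        "cluster_category": truth.cluster_category,
        "shared_fraction": truth.shared_fraction,
        "location": truth.location,
        "hsi": truth.hsi,
        "wgd": truth.wgd,
        "polyclonal": truth.polyclonal,
        "hypermutator": truth.hypermutator,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    return out / "manifest.yaml"


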