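"""Cancer cell fractions, multi-sample mutation clustering and cluster
categories.

The cancer cell fraction (CCF) of a mutation in a sample follows from the
variant allele fraction through

    VAF = p * CCF / (CPNnorm * (1 - p) + p * CPNmut)

with tumor purity ``p``, local tumor copy number ``CPNmut`` and normal copy
number ``CPNnorm`` (2 on autosomes); one mutated copy per carrying cell is
assumed. Mutations are grouped by shared CCF vectors across the patient's
samples with a finite binomial mixture: cluster k has one CCF per sample,
each mutation's alt count is Binomial(depth, a * CCF_k) where ``a`` is its
locus-specific VAF-per-CCF factor, and the mixture is fitted by EM with
K-means initialisation, model size chosen by BIC over K = 1..8.

Clusters containing less than 5/1000 of the patient's mutations, or only
silent mutations, are filtered out before downstream interpretation.
Categories follow the paired-recurrence schemes: for clonally related
(ancestral) pairs, the trunk clone (shared, CCF > 0.8 everywhere), trunk
subclones (shared, lower CCF) and primary/recurrence branches; for de novo
pairs, per-tumor clones and subclones; for multi-region cases, trunk /
branch / leaf subclones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .harmonize import HarmonizedCase
from .io import local_copy_number_batch


@dataclass
class MutationCluster:
    cluster_id: str
    member_rows: np.ndarray  # row indices into the case mutation table
    ccf: pd.Series  # per-sample CCF center
    size: int
    silent_only: bool


@dataclass
class CategoryAssignment:
    scheme: str  # "ancestral" | "de_novo" | "multi_region"
    categories: dict[str, str]  # cluster id -> category


def compute_ccf(vaf: float, purity: float, cn_mut: float, cn_norm: float = 2.0, clip: bool = True):
    """Invert the VAF formula: CCF = VAF * (cn_norm*(1-p) + p*cn_mut) / p."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    vaf_arr = np.asarray(vaf, dtype=float)
    cn_arr = np.asarray(cn_mut, dtype=float)
    if np.any((cn_arr < 1) & (vaf_arr > 0)):
        raise ValueError("cn_mut < 1 at a locus with VAF > 0")
    ccf = vaf_arr * (cn_norm * (1 - purity) + purity * cn_arr) / purity
    if clip:
        ccf = np.clip(ccf, 0.0, 1.0)
    return float(ccf) if np.isscalar(vaf) else ccf


def expected_vaf(ccf, purity: float, cn_mut, cn_norm: float = 2.0):
    """Forward VAF formula (the inverse of :func:`compute_ccf`)."""
    ccf = np.asarray(ccf, dtype=float)
    cn_mut = np.asarray(cn_mut, dtype=float)
    return purity * ccf / (cn_norm * (1 - purity) + purity * cn_mut)


def ccf_factors(harmonized: HarmonizedCase) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alt, depth, a) over union mutations x tumor samples.

    ``a`` is the per-locus VAF-per-unit-CCF factor
    ``p / (2*(1-p) + p*cn_mut)`` using each sample's purity and local copy
    number (fallback round(ploidy) outside segments).
    """
    case = harmonized.case
    rows = harmonized.union_rows()
    chroms = case.mutations["chrom"].to_numpy(dtype=object)[rows]
    pos = case.mutations["pos"].to_numpy(np.int64)[rows]
    samples = harmonized.tumor_samples
    alt = np.zeros((len(rows), len(samples)), dtype=np.int64)
    depth = np.zeros_like(alt)
    a = np.zeros((len(rows), len(samples)))
    full_depth = case.depth()
    for j, sample in enumerate(samples):
        cj = case.sample_index(sample)
        prof = case.profile(sample)
        fallback = int(round(prof.ploidy)) if prof.ploidy else 2
        seg = case.segments.get(sample, pd.DataFrame(columns=["chrom", "start", "end", "total_cn"]))
        cn = np.maximum(local_copy_number_batch(seg, chroms, pos, fallback=fallback), 1)
        p = prof.purity
        a[:, j] = p / (2.0 * (1 - p) + p * cn)
        alt[:, j] = case.alt_reads[rows, cj]
        depth[:, j] = full_depth[rows, cj]
    return alt, depth, a


def cluster_mutations(
    harmonized: HarmonizedCase,
    seed: int = 0,
    max_k: int = 8,
    restarts: int = 3,
    max_iter: int = 60,
    tol: float = 1e-5,
    merge_tol: float = 0.08,
) -> list[MutationCluster]:
    """Cluster the union mutation set by shared per-sample CCFs.

    Binomial-mixture EM over per-sample read counts with shared cluster CCF
    vectors; K selected by BIC over 1..``max_k`` with K-means initialisation
    on observed per-mutation CCFs. Because a mutation only enters the union
    set if it clears the caller's thresholds (>= 3 reads, >= 5% VAF, >= 10x)
    in at least one sample, naive centers of low-CCF clusters are biased
    upward and shared clusters can split by detection pattern; centers are
    therefore re-estimated under the inclusion-conditioned likelihood
    (detection modelled with Poisson read-count tails), and components whose
    debiased centers agree within ``merge_tol`` in every sample are merged.
    Deterministic under ``seed``.
    """
    alt, depth, a = ccf_factors(harmonized)
    if not (depth > 0).any():
        raise ValueError("all-zero depths: nothing to cluster")
    n, S = alt.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_ccf = np.clip(np.where(depth > 0, alt / np.maximum(depth, 1), 0.0) / np.maximum(a, 1e-9), 0.0, 1.0)

    # saturated per-mutation loglik, for deviance-guided split seeding
    with np.errstate(invalid="ignore", divide="ignore"):
        q_hat = np.clip(np.where(depth > 0, alt / np.maximum(depth, 1), 0.0), 0.0, 1.0)
        sat = np.where(alt > 0, alt * np.log(np.maximum(q_hat, 1e-300)), 0.0)
        sat += np.where(depth - alt > 0, (depth - alt) * np.log(np.maximum(1 - q_hat, 1e-300)), 0.0)
    sat_ll = sat.sum(axis=1)

    # upward sweep with deviance- and censoring-guided split seeds
    best = None
    prev = None
    for K in range(1, min(max_k, n) + 1):
        inits = _split_inits(prev, alt, depth, a, obs_ccf, sat_ll) if prev is not None else None
        fit = _fit_binomial_mixture(
            alt, depth, a, obs_ccf, K, seed, restarts, max_iter, tol, init_centers=inits
        )
        prev = fit
        if best is None or fit["bic"] < best["bic"]:
            best = fit
    # downward prune from the richest fit: overfitting then removing the
    # weakest component finds small censored modes the upward path misses
    fit = prev
    while fit["centers"].shape[0] > 1:
        pi = fit["pi"]
        keep = np.argsort(pi)[1:]
        init = fit["centers"][np.sort(keep)]
        fit = _fit_binomial_mixture(
            alt, depth, a, obs_ccf, init.shape[0], seed, 0, max_iter, tol, init_centers=[init]
        )
        if fit["bic"] < best["bic"]:
            best = fit
    labels, centers = _merge_close(best["labels"], best["centers"], merge_tol)

    rows = harmonized.union_rows()
    effects = harmonized.case.mutations["effect"].to_numpy(dtype=object)
    clusters = []
    for k in range(centers.shape[0]):
        members = np.flatnonzero(labels == k)
        if len(members) == 0:
            continue
        silent_only = bool(np.all(effects[rows[members]] == "silent"))
        clusters.append(
            MutationCluster(
                cluster_id=f"K{len(clusters)}",
                member_rows=rows[members],
                ccf=pd.Series(centers[k], index=harmonized.tumor_samples),
                size=len(members),
                silent_only=silent_only,
            )
        )
    clusters.sort(key=lambda c: (-float(c.ccf.sum()), -c.size))
    for i, c in enumerate(clusters):
        c.cluster_id = f"K{i}"
    return clusters


def _split_inits(prev_fit, alt, depth, a, obs_ccf, sat_ll):
    """Warm starts for K+1 from the previous fit.

    One candidate adds a component at the median observed CCF of the
    globally worst-explained (highest-deviance) mutations; one candidate
    per previous component splits that component at its own worst-explained
    members — the route by which small, heavily censored clusters hidden
    inside a larger component are found.
    """
    centers = prev_fit["centers"]
    pi = prev_fit["pi"]
    labels = prev_fit["labels"]
    ll_n = _log_resp(alt, depth, a, centers, pi)[0].max(axis=1)
    dev = sat_ll - ll_n
    inits = []
    worst = np.argsort(dev)[-max(10, len(dev) // 20):]
    inits.append(np.vstack([centers, np.median(obs_ccf[worst], axis=0)[None, :]]))
    # split the single worst-fitting component at its own deviance tail
    K = centers.shape[0]
    if K >= 2:
        per_cluster_dev = np.array(
            [dev[labels == k].mean() if (labels == k).any() else 0.0 for k in range(K)]
        )
        k = int(np.argmax(per_cluster_dev))
        members = np.flatnonzero(labels == k)
        if len(members) >= 20:
            tail = members[np.argsort(dev[members])][-max(10, len(members) // 5):]
            inits.append(np.vstack([centers, np.median(obs_ccf[tail], axis=0)[None, :]]))
    # censoring-aware candidates: a low-CCF cluster whose members mostly miss
    # the caller's thresholds is observed only through its upper tail and is
    # geometrically indistinguishable from a mid-CCF cluster; offer a
    # half-CCF component next to the lowest non-root components so the
    # truncation-corrected likelihood can adjudicate
    nonzero_low = np.argsort(np.where(centers.max(axis=1) > 0.1, centers.sum(axis=1), np.inf))
    for k in nonzero_low[: min(2, K)]:
        if not np.isfinite(centers[k].sum()) or centers[k].max() <= 0.1:
            continue
        inits.append(np.vstack([centers, (centers[k] * 0.45)[None, :]]))
    return inits


def _fit_binomial_mixture(alt, depth, a, obs_ccf, K, seed, restarts, max_iter, tol, init_centers=None):
    """Truncated binomial-mixture EM.

    The union set only contains mutations called in at least one sample, so
    the observed data follow the mixture *conditioned on inclusion*. The
    E-step divides each component density by its inclusion probability
    P(called somewhere | cluster CCFs), and the M-step augments the observed
    members with the expected censored mass and its censored read-count
    means — the standard missing-data EM for truncated mixtures. Without
    this, low-CCF cluster centers are biased upward and shared clusters
    split along detection patterns.
    """
    n, S = alt.shape
    best = None
    inits = []
    for r in range(restarts):
        if K == 1:
            inits.append(obs_ccf.mean(axis=0, keepdims=True))
            break
        km = KMeans(n_clusters=K, n_init=2, random_state=seed + 977 * r)
        km.fit(obs_ccf)
        inits.append(np.clip(km.cluster_centers_, 0.0, 1.0))
    for extra in init_centers or []:
        if extra.shape[0] == K:
            inits.append(np.clip(extra, 0.0, 1.0))
    da = depth * a
    for centers in inits:
        centers = centers.copy()
        pi = np.full(K, 1.0 / K)
        prev = -np.inf
        for _ in range(max_iter):
            logp, trunc = _log_resp(alt, depth, a, centers, pi)
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            # observed-data loglik: inclusion is a deterministic function of
            # the observed counts, so the responsibilities use the plain
            # component densities; the truncation enters only through the
            # P(included) normalizer...
            p_incl_mix = np.zeros(n)
            for k in range(K):
                p_incl_mix += pi[k] * (trunc[k][0] if trunc[k] is not None else 1.0)
            ll = float(lse.sum() - np.log(np.maximum(p_incl_mix, 1e-12)).sum())
            resp = np.exp(logp - lse[:, None])
            # ...and through the censored-mass augmentation of the M step
            num = np.empty((K, S))
            den = np.empty((K, S))
            mass = np.empty(K)
            for k in range(K):
                r_k = resp[:, k]
                if trunc[k] is None:
                    num[k] = r_k @ alt
                    den[k] = r_k @ da
                    mass[k] = r_k.sum()
                else:
                    p_incl, mu_miss = trunc[k]
                    ratio = np.clip((1.0 - p_incl) / p_incl, 0.0, 50.0)
                    w_k = r_k * ratio
                    num[k] = r_k @ alt + w_k @ mu_miss
                    den[k] = (r_k + w_k) @ da
                    mass[k] = r_k.sum() + w_k.sum()
            pi = np.maximum(mass / mass.sum(), 1e-12)
            pi = pi / pi.sum()
            centers = np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), 0.0), 0.0, 1.0)
            if ll - prev < tol * max(1.0, abs(ll)):
                prev = ll
                break
            prev = ll
        if best is None or prev > best["ll"]:
            logp, _ = _log_resp(alt, depth, a, centers, pi)
            best = {"ll": prev, "centers": centers, "pi": pi, "labels": np.argmax(logp, axis=1)}
    k_params = K * S + (K - 1)
    best["bic"] = -2.0 * best["ll"] + k_params * np.log(max(n, 2))
    return best


# mean per-cluster expected alt count above which detection is effectively
# certain and the truncation correction is skipped
_TRUNC_LAMBDA = 20.0


def _log_resp(alt, depth, a, centers, pi):
    """Log responsibilities plus per-component truncation statistics.

    Returns ``(logp, trunc)``: the (n, K) unnormalized log responsibilities
    (binomial coefficient omitted — constant across components) and, per
    component, either None (detection effectively certain) or the tuple
    ``(P_incl, censored alt means)`` used by the likelihood normalizer and
    the censored-mass M step.
    """
    n, S = alt.shape
    K = centers.shape[0]
    out = np.empty((n, K))
    trunc: list = [None] * K
    for k in range(K):
        q = np.clip(a * centers[k][None, :], 1e-15, 1 - 1e-12)
        out[:, k] = (alt * np.log(q) + (depth - alt) * np.log1p(-q)).sum(axis=1) + np.log(pi[k])
        lam = depth * q
        if lam.mean(axis=0).max() < _TRUNC_LAMBDA:
            trunc[k] = _inclusion_stats(depth, lam)
    return out, trunc


def _inclusion_stats(depth, lam, min_alt=3, min_vaf=0.05, min_depth=10):
    """Union-inclusion probability and censored alt means, Poisson tails.

    A site is called in a sample iff alt >= max(min_alt, ceil(min_vaf*depth))
    at >= ``min_depth`` coverage; inclusion in the union requires a call in
    at least one sample. Censored means are E[alt | alt below threshold] per
    sample — the expected read support of the mutations the caller missed.
    """
    from scipy.special import gammainc

    t = np.maximum(min_alt, np.ceil(min_vaf * depth))
    lam = np.maximum(lam, 1e-12)
    p_call = np.where(depth >= min_depth, gammainc(t, lam), 0.0)
    p_miss = np.clip(1.0 - p_call, 1e-12, 1.0)
    p_incl = np.clip(1.0 - np.exp(np.log(p_miss).sum(axis=1)), 1e-3, 1.0)
    # E[X 1(X < t)] = lam * P(X <= t-2) for X ~ Poisson(lam)
    below = lam * (1.0 - gammainc(t - 1.0, lam))
    mu_miss = below / p_miss
    return p_incl, mu_miss


def _detection_prob(depth, q, min_alt=3, min_vaf=0.05, min_depth=10):
    """P(a site is called) given depth and expected VAF, Poisson tail model."""
    from scipy.special import gammainc

    t = np.maximum(min_alt, np.ceil(min_vaf * depth))
    lam = depth * q
    p = gammainc(t, np.maximum(lam, 1e-300))
    return np.where(depth >= min_depth, p, 0.0)


def _detection_prob(depth, q, min_alt=3, min_vaf=0.05, min_depth=10):
    """P(a site is called) given depth and expected VAF, Poisson tail model.

    Calling requires alt >= max(min_alt, ceil(min_vaf*depth)) at >= min_depth
    coverage; the binomial alt count is approximated Poisson(depth*q), which
    is accurate in the low-VAF regime where detection is actually uncertain.
    """
    from scipy.special import gammainc

    t = np.maximum(min_alt, np.ceil(min_vaf * depth))
    lam = depth * q
    p = gammainc(t, np.maximum(lam, 1e-300))
    return np.where(depth >= min_depth, p, 0.0)


def _merge_close(labels, centers, merge_tol):
    """Union-find merge of components whose centers agree within
    ``merge_tol`` in every sample; merged centers are size-weighted means."""
    K = centers.shape[0]
    parent = list(range(K))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(K):
        for j in range(i + 1, K):
            if np.all(np.abs(centers[i] - centers[j]) <= merge_tol):
                parent[find(j)] = find(i)
    groups = {}
    for k in range(K):
        groups.setdefault(find(k), []).append(k)
    sizes = np.bincount(labels, minlength=K).astype(float)
    new_centers = []
    remap = np.empty(K, dtype=np.int64)
    for new_k, (root, members) in enumerate(sorted(groups.items())):
        w = sizes[members]
        if w.sum() > 0:
            new_centers.append((centers[members] * w[:, None]).sum(axis=0) / w.sum())
        else:
            new_centers.append(centers[root])
        for m in members:
            remap[m] = new_k
    return remap[labels], np.asarray(new_centers)


def filter_clusters(
    clusters: Sequence[MutationCluster],
    total_mutations: int,
    min_fraction: float = 0.005,
) -> list[MutationCluster]:
    """Drop clusters below 5/1000 of the patient's mutations (strict) or
    containing only silent mutations."""
    if total_mutations < 1:
        raise ValueError("total_mutations must be >= 1")
    kept = [
        c
        for c in clusters
        if c.size >= min_fraction * total_mutations and not c.silent_only
    ]
    if not kept:
        warnings.warn("all mutation clusters were filtered out")
    return kept


def classify_cluster_categories(
    clusters: Sequence[MutationCluster],
    roles: dict[str, str],
    scheme: str,
    clonal_thr: float = 0.8,
    presence_thr: float = 0.05,
) -> CategoryAssignment:
    """Assign clonal/subclonal categories per cluster.

    A cluster is *present* in a sample iff its CCF center is >=
    ``presence_thr``; it is a *clone* iff present in all required samples
    with every CCF strictly above ``clonal_thr``. When several clusters
    qualify as the clone, the one with the highest minimum CCF keeps the
    title and the rest become subclones.
    """
    samples = list(clusters[0].ccf.index) if clusters else []
    primaries = [s for s in samples if roles.get(s) == "primary"]
    recurrents = [s for s in samples if roles.get(s) == "recurrent"]
    if scheme not in ("ancestral", "de_novo", "multi_region"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme in ("ancestral", "multi_region") and (not primaries or not recurrents):
        raise ValueError("scheme requires primary and recurrent samples")
    categories: dict[str, str] = {}

    def present(c, group):
        return all(c.ccf[s] >= presence_thr for s in group)

    def clonal(c, group):
        return all(c.ccf[s] > clonal_thr for s in group)

    if scheme in ("ancestral", "multi_region"):
        shared = [c for c in clusters if present(c, primaries) and present(c, recurrents)]
        clone_cands = [c for c in shared if clonal(c, primaries + recurrents)]
        trunk_clone = max(clone_cands, key=lambda c: float(c.ccf.min()), default=None)
        for c in clusters:
            if c is trunk_clone:
                categories[c.cluster_id] = "trunk_clone"
            elif c in shared:
                categories[c.cluster_id] = "trunk_subclone"
            elif scheme == "ancestral":
                in_p = any(c.ccf[s] >= presence_thr for s in primaries)
                categories[c.cluster_id] = "primary_branch" if in_p else "recurrence_branch"
            else:
                n_present = sum(c.ccf[s] >= presence_thr for s in samples)
                categories[c.cluster_id] = "leaf_subclone" if n_present <= 1 else "branch_subclone"
    else:  # de novo: per-tumor clones and subclones
        for side, group, prefix in (("p", primaries, "primary"), ("r", recurrents, "recurrence")):
            side_clusters = [c for c in clusters if any(c.ccf[s] >= presence_thr for s in group)]
            clone_cands = [c for c in side_clusters if clonal(c, group)]
            clone = max(clone_cands, key=lambda c: float(c.ccf[group].min()), default=None)
            for c in side_clusters:
                label = f"{prefix}_clone" if c is clone else f"{prefix}_subclone"
                # a cluster presenting in both tumors (hotspot coincidence)
                # keeps its first assignment
                categories.setdefault(c.cluster_id, label)
    return CategoryAssignment(scheme=scheme, categories=categories)
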