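"""Clonal relatedness of paired tumors: clonality index, calibrated cutoff,
recurrence pattern and location, breakpoint sharing, WGD and gene CNV calls.

The clonality index (CI) quantifies how unlikely the set of mutations shared
by two tumors is to have co-occurred by chance. For each shared
nonsynonymous mutation ``m`` with population frequency ``p_m`` (its
occurrence count over the total mutation count of a background cohort), the
chance of independent co-occurrence in both tumors is the binomial
``P(X) = C_2^2 p_m^2 (1-p_m)^0 = p_m^2``; the CI is
``-log10 prod_m P(X)_m = -2 sum_m log10 p_m``, accumulated in log space.
Unrelated pairs share only common hotspots (small CI); clonally related
pairs share many rare mutations (large CI).

The decision cutoff is calibrated on a cohort of unrelated tumors:
positive controls subsample each tumor's mutation set at 40/60/80% in
duplicate (simulating heterogeneous but related pairs), negative controls
draw an equivalent number of unrelated tumor pairs; the accuracy-maximizing
threshold is recorded per repeat and the median over repeats is the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CohortCatalog


@dataclass
class ClonalityResult:
    ci: float
    n_shared: int
    p_values: dict
    pattern: Optional[str] = None
    cutoff: Optional[float] = None


@dataclass
class CalibrationResult:
    cutoffs: np.ndarray  # per-repeat optimal cutoffs
    cutoff: float  # median of the per-repeat optima
    fractions: tuple[float, ...]
    n_positive_pairs: int  # per repeat
    n_negative_pairs: int  # per repeat
    accuracy: float  # at the median cutoff, over all pairs pooled


@dataclass
class LocationResult:
    hsi: int
    location: str  # "local" | "distant"


def mutation_probability(key, catalog: CohortCatalog) -> float:
    """Population frequency of a mutation: count / total cohort mutations.

    Keys never observed in the catalog get a pseudo-count of 1 — the most
    conservative nonzero frequency; rarer shared mutations are stronger
    evidence of relatedness, so the floor keeps unseen keys informative
    without dividing by zero.
    """
    if catalog.n_total <= 0 or not catalog.counts:
        raise ValueError("empty catalog")
    count = catalog.counts.get(key, 0)
    return max(count, 1) / catalog.n_total


def clonality_index(shared_nonsyn_keys: Sequence, catalog: CohortCatalog) -> ClonalityResult:
    """CI over shared nonsynonymous mutation keys; empty set gives CI 0."""
    keys = list(shared_nonsyn_keys)
    p_values = {k: mutation_probability(k, catalog) for k in keys}
    ci = float(-2.0 * sum(np.log10(p) for p in p_values.values())) if keys else 0.0
    return ClonalityResult(ci=ci, n_shared=len(keys), p_values=p_values)


def classify_recurrence(ci: float, cutoff: float) -> str:
    """Ancestral iff CI >= cutoff (ties classified ancestral), else de novo."""
    return "ancestral" if ci >= cutoff else "de_novo"


def calibrate_ci_cutoff(
    per_tumor_sets: Sequence[np.ndarray],
    fractions: tuple[float, ...] = (0.40, 0.60, 0.80),
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
) -> CalibrationResult:
    """Calibrate the CI cutoff on a cohort of unrelated tumors.

    Per repeat: for every tumor and every fraction, two independent
    subsamples form a related (positive) pair — ``len(fractions) * n``
    positive pairs; the same number of random unrelated tumor pairs form the
    negatives. The accuracy-maximizing threshold (swept at midpoints between
    sorted observed CI values, ties broken toward the smaller cutoff) is the
    repeat's optimum; the calibrated cutoff is the median over repeats.

    Population frequencies are taken from the aggregation of
    ``per_tumor_sets`` themselves — the calibration cohort is its own
    background catalog.
    """
    n = len(per_tumor_sets)
    if n < 2:
        raise ValueError("need at least two tumors to calibrate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # factorize keys across tumors; per-key CI contribution 2*(log10 N - log10 count)
    lengths = [len(np.unique(np.asarray(s))) for s in per_tumor_sets]
    sets_u = [np.unique(np.asarray(s)) for s in per_tumor_sets]
    all_keys = np.concatenate(sets_u)
    uniq, inv, counts = np.unique(all_keys, return_inverse=True, return_counts=True)
    n_total = int(sum(lengths))
    contrib = 2.0 * (np.log10(n_total) - np.log10(counts))
    # per-tumor arrays of factorized ids (sorted) and aligned contributions;
    # tumors are put in a canonical content order so the calibrated cutoff is
    # invariant to the order the caller lists them in
    ids = np.split(inv, np.cumsum(lengths)[:-1])
    canon = sorted(range(n), key=lambda t: (lengths[t], ids[t].tobytes()))
    ids = [ids[t] for t in canon]
    lengths = [lengths[t] for t in canon]
    contribs = [contrib[i] for i in ids]

    def pair_ci(ids_a, contrib_a, ids_b):
        loc = np.searchsorted(ids_b, ids_a)
        loc = np.clip(loc, 0, len(ids_b) - 1)
        hit = ids_b[loc] == ids_a
        return float(contrib_a[hit].sum())

    optima = np.empty(repeats)
    pos_all, neg_all = [], []
    n_pos = len(fractions) * n
    for rep in range(repeats):
        pos = np.empty(n_pos)
        i = 0
        for t in range(n):
            m = lengths[t]
            for f in fractions:
                k = int(round(f * m))
                m1 = np.zeros(m, dtype=bool)
                m1[rng.permutation(m)[:k]] = True
                m2 = np.zeros(m, dtype=bool)
                m2[rng.permutation(m)[:k]] = True
                pos[i] = contribs[t][m1 & m2].sum()
                i += 1
        neg = np.empty(n_pos)
        for i in range(n_pos):
            a, b = rng.choice(n, size=2, replace=False)
            neg[i] = pair_ci(ids[a], contribs[a], ids[b])
        optima[rep] = _accuracy_optimal_cutoff(pos, neg)
        pos_all.append(pos)
        neg_all.append(neg)

    cutoff = float(np.median(optima))
    pos_all = np.concatenate(pos_all)
    neg_all = np.concatenate(neg_all)
    accuracy = float(((pos_all >= cutoff).sum() + (neg_all < cutoff).sum()) / (len(pos_all) + len(neg_all)))
    return CalibrationResult(
        cutoffs=optima,
        cutoff=cutoff,
        fractions=tuple(fractions),
        n_positive_pairs=n_pos,
        n_negative_pairs=n_pos,
        accuracy=accuracy,
    )


def _accuracy_optimal_cutoff(pos: np.ndarray, neg: np.ndarray) -> float:
    """Threshold maximizing accuracy of (CI >= cutoff -> related).

    Candidates are midpoints between consecutive sorted observed values,
    plus sentinels below/above all values; ties prefer the smaller cutoff.
    """
    values = np.unique(np.concatenate([pos, neg]))
    if len(values) == 1:
        return float(values[0])
    candidates = np.concatenate([[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = len(pos) - np.searchsorted(pos_sorted, candidates, side="left")
    tn = np.searchsorted(neg_sorted, candidates, side="left")
    acc = (tp + tn) / (len(pos) + len(neg))
    best = np.flatnonzero(acc == acc.max())[0]  # first = smallest cutoff
    return float(candidates[best])


# ---------------------------------------------------------------------------
# recurrence location


def hepatic_segment_interval(primary_segments: set[int], recurrent_segments: set[int]) -> int:
    """Minimum Couinaud-segment distance between the two tumors, capped at 4."""
    for segs in (primary_segments, recurrent_segments):
        if not segs:
            raise ValueError("empty hepatic segment set")
        for s in segs:
            if not 1 <= int(s) <= 8:
                raise ValueError(f"hepatic segment {s} outside 1-8")
    hsi = min(abs(int(a) - int(b)) for a in primary_segments for b in recurrent_segments)
    return min(hsi, 4)


def classify_location(hsi: int) -> LocationResult:
    """Local recurrence iff the hepatic segment interval is 0 or 1."""
    return LocationResult(hsi=int(hsi), location="local" if hsi <= 1 else "distant")


# ---------------------------------------------------------------------------
# breakpoints, ploidy, gene-level CNV


def shared_breakpoints(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    tolerance_bp: int = 10,
    bp_type: Optional[str] = None,
) -> int:
    """Count breakpoints of A matched in B.

    Two breakpoints match iff they have the same type, the same (unordered)
    chromosome pair, and both positions within ``tolerance_bp``.
    """
    cols = ["type", "chrom1", "pos1", "chrom2", "pos2"]
    a = table_a[cols].copy() if len(table_a) else pd.DataFrame(columns=cols)
    b = table_b[cols].copy() if len(table_b) else pd.DataFrame(columns=cols)
    if bp_type is not None:
        a = a[a["type"] == bp_type]
        b = b[b["type"] == bp_type]
    count = 0
    for ra in a.itertuples(index=False):
        for rb in b.itertuples(index=False):
            if ra.type != rb.type:
                continue
            direct = (
                ra.chrom1 == rb.chrom1
                and ra.chrom2 == rb.chrom2
                and abs(ra.pos1 - rb.pos1) <= tolerance_bp
                and abs(ra.pos2 - rb.pos2) <= tolerance_bp
            )
            swapped = (
                ra.chrom1 == rb.chrom2
                and ra.chrom2 == rb.chrom1
                and abs(ra.pos1 - rb.pos2) <= tolerance_bp
                and abs(ra.pos2 - rb.pos1) <= tolerance_bp
            )
            if direct or swapped:
                count += 1
                break
    return count


def call_wgd(ploidy: float) -> bool:
    """Whole-genome doubling iff ploidy strictly exceeds 2.9."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return ploidy > 2.9


def classify_gene_cnv(total_cn: int, median_ploidy: float) -> str:
    """Gene-level CNV class relative to the median ploidy.

    deletion (cn 0) > amplification (cn > 2x ploidy) > gain (cn > ploidy) >
    loss (cn < ploidy) > neutral, in that precedence.
    """
    if total_cn < 0:
        raise ValueError("negative copy number")
    if total_cn == 0:
        return "deletion"
    if total_cn > 2 * median_ploidy:
        return "amplification"
    if total_cn > median_ploidy:
        return "gain"
    if total_cn < median_ploidy:
        return "loss"
    return "neutral"
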