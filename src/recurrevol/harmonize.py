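"""Mutation-set harmonization across a patient's samples.

Four steps make the per-sample mutation sets comparable before any
evolutionary inference:

1. *high-confidence filter* — keep a called variant only with >=10x depth in
   tumor and normal, tumor VAF >= 5%, normal VAF < 1% (strict) and at least
   3 supporting tumor reads;
2. *CNV drop* — a mutation present in one sample but absent from another
   sample whose locus lies in a copy-number-loss region (cn <= 1) is
   excluded from every sample (its absence is explainable by the loss, so
   its sharing status is uninformative);
3. *force calling* — for every key in the patient's aggregate set, a sample
   lacking a call recovers the mutation if covered >=10x with >=2
   supporting reads;
4. *shared/private partition* — per-pair shared fractions, Jaccard index,
   and the random-pair null distribution.

Statuses per (mutation, sample) are ``absent``, ``called``,
``force_called`` or ``cnv_dropped``; every status change is recorded in an
audit log from which the final sets can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import local_copy_number_batch
from .types import PatientCase

ABSENT, CALLED, FORCE_CALLED, CNV_DROPPED = 0, 1, 2, 3
STATUS_NAMES = {ABSENT: "absent", CALLED: "called", FORCE_CALLED: "force_called", CNV_DROPPED: "cnv_dropped"}


@dataclass
class HarmonizedCase:
    """Final per-sample mutation sets with full status provenance."""

    case: PatientCase
    status: np.ndarray  # (n_mut, n_tumor_samples) int
    tumor_samples: list[str]
    audit: pd.DataFrame  # columns: step, mut_index, sample, old, new

    def sample_set(self, sample: str) -> np.ndarray:
        """Row indices of mutations in the sample's final set."""
        j = self.tumor_samples.index(sample)
        col = self.status[:, j]
        return np.flatnonzero((col == CALLED) | (col == FORCE_CALLED))

    def final_sets(self) -> dict[str, np.ndarray]:
        return {
            s: np.flatnonzero((self.status[:, j] == CALLED) | (self.status[:, j] == FORCE_CALLED))
            for j, s in enumerate(self.tumor_samples)
        }

    def union_rows(self) -> np.ndarray:
        present = (self.status == CALLED) | (self.status == FORCE_CALLED)
        return np.flatnonzero(present.any(axis=1))


def filter_high_confidence(
    case: PatientCase,
    min_depth: int = 10,
    min_tumor_vaf: float = 0.05,
    max_normal_vaf: float = 0.01,
    min_alt_reads: int = 3,
) -> np.ndarray:
    """High-confidence call mask over (mutation, tumor sample).

    Keeps a called variant iff tumor depth >= 10, normal depth >= 10, tumor
    VAF >= 5%, normal VAF < 1% (strict) and >= 3 supporting tumor reads.
    Sites without an assayed normal (depth 0) are excluded.
    """
    tumor_idx = [case.sample_index(s) for s in case.tumor_samples]
    nj = case.sample_index(case.normal_sample)
    depth = case.depth()
    n_alt = case.alt_reads[:, nj].astype(float)
    n_depth = depth[:, nj].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_vaf = np.where(n_depth > 0, n_alt / np.maximum(n_depth, 1), np.nan)
    keep = np.zeros((len(case.mutations), len(tumor_idx)), dtype=bool)
    for out_j, j in enumerate(tumor_idx):
        t_alt = case.alt_reads[:, j].astype(float)
        t_depth = depth[:, j].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_vaf = np.where(t_depth > 0, t_alt / np.maximum(t_depth, 1), 0.0)
        keep[:, out_j] = (
            case.called[:, j]
            & (t_depth >= min_depth)
            & (n_depth >= min_depth)
            & (t_vaf >= min_tumor_vaf)
            & (n_vaf < max_normal_vaf)
            & (t_alt >= min_alt_reads)
        )
    return keep


def harmonize_case(
    case: PatientCase,
    min_depth: int = 10,
    force_min_alt: int = 2,
    cnv_loss_cn: int = 1,
) -> HarmonizedCase:
    """Run the full harmonization: filter, CNV drop, then force calling."""
    tumor_samples = case.tumor_samples
    hc = filter_high_confidence(case, min_depth=min_depth)
    status = np.where(hc, CALLED, ABSENT).astype(np.int8)
    audit_parts = [_audit_frame("high_confidence", np.zeros_like(status), status, tumor_samples)]

    before = status.copy()
    status = apply_cnv_drop(case, status, cnv_loss_cn=cnv_loss_cn)
    audit_parts.append(_audit_frame("cnv_drop", before, status, tumor_samples))

    before = status.copy()
    status = apply_force_calling(case, status, min_depth=min_depth, min_alt=force_min_alt)
    audit_parts.append(_audit_frame("force_calling", before, status, tumor_samples))

    audit = pd.concat(audit_parts, ignore_index=True)
    return HarmonizedCase(case=case, status=status, tumor_samples=list(tumor_samples), audit=audit)


def apply_cnv_drop(case: PatientCase, status: np.ndarray, cnv_loss_cn: int = 1) -> np.ndarray:
    """Exclude mutations whose absence coincides with copy-number loss.

    A mutation present in some sample A and absent in some sample B is
    removed from *all* samples iff the local copy number in B at its locus
    is <= ``cnv_loss_cn``. Unsegmented loci fall back to round(ploidy).
    """
    status = status.copy()
    tumor_samples = case.tumor_samples
    chroms = case.mutations["chrom"].to_numpy(dtype=object)
    pos = case.mutations["pos"].to_numpy(np.int64)
    present = status >= CALLED
    any_present = present.any(axis=1)
    drop = np.zeros(len(pos), dtype=bool)
    for j, sample in enumerate(tumor_samples):
        absent_here = any_present & ~present[:, j]
        if not absent_here.any():
            continue
        prof = case.profile(sample)
        fallback = int(round(prof.ploidy)) if prof.ploidy else 2
        seg = case.segments.get(sample, pd.DataFrame(columns=["chrom", "start", "end", "total_cn"]))
        idx = np.flatnonzero(absent_here)
        cn = local_copy_number_batch(seg, chroms[idx], pos[idx], fallback=fallback)
        drop[idx[cn <= cnv_loss_cn]] = True
    status[drop, :] = np.where(present[drop, :], CNV_DROPPED, ABSENT)
    return status


def apply_force_calling(
    case: PatientCase,
    status: np.ndarray,
    min_depth: int = 10,
    min_alt: int = 2,
) -> np.ndarray:
    """Recover uncalled mutations with sufficient coverage and support.

    The aggregate key set is the union over the patient's samples of
    currently present mutations; for each sample lacking a call at an
    aggregate key, the mutation is added iff tumor depth >= ``min_depth``
    and alt reads >= ``min_alt``. Force calling only ever adds.
    """
    status = status.copy()
    present = status >= CALLED
    dropped = (status == CNV_DROPPED).any(axis=1)
    aggregate = present.any(axis=1) & ~dropped
    depth = case.depth()
    for j, sample in enumerate(case.tumor_samples):
        cj = case.sample_index(sample)
        candidate = aggregate & (status[:, j] == ABSENT)
        recover = candidate & (depth[:, cj] >= min_depth) & (case.alt_reads[:, cj] >= min_alt)
        status[recover, j] = FORCE_CALLED
    return status


def _audit_frame(step: str, before: np.ndarray, after: np.ndarray, samples: Sequence[str]) -> pd.DataFrame:
    rows, cols = np.nonzero(before != after)
    return pd.DataFrame(
        {
            "step": step,
            "mut_index": rows,
            "sample": np.asarray(samples, dtype=object)[cols],
            "old": [STATUS_NAMES[v] for v in before[rows, cols]],
            "new": [STATUS_NAMES[v] for v in after[rows, cols]],
        }
    )


def replay_audit(n_mut: int, tumor_samples: Sequence[str], audit: pd.DataFrame) -> np.ndarray:
    """Rebuild the status matrix from the audit log alone."""
    status = np.zeros((n_mut, len(tumor_samples)), dtype=np.int8)
    name_to_code = {v: k for k, v in STATUS_NAMES.items()}
    col = {s: j for j, s in enumerate(tumor_samples)}
    for r in audit.itertuples(index=False):
        status[r.mut_index, col[r.sample]] = name_to_code[r.new]
    return status


# ---------------------------------------------------------------------------
# sharing statistics


def shared_partition(set_a: np.ndarray, set_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(shared, private to A, private to B) over normalized key arrays."""
    a = np.unique(np.asarray(set_a))
    b = np.unique(np.asarray(set_b))
    shared = np.intersect1d(a, b, assume_unique=True)
    return shared, np.setdiff1d(a, shared, assume_unique=True), np.setdiff1d(b, shared, assume_unique=True)


def shared_fraction(set_a: np.ndarray, set_b: np.ndarray) -> tuple[float, float, float]:
    """Per-set shared fractions and their mean; empty sets give 0."""
    a = np.unique(np.asarray(set_a))
    b = np.unique(np.asarray(set_b))
    n_shared = len(np.intersect1d(a, b, assume_unique=True))
    f_a = n_shared / len(a) if len(a) else 0.0
    f_b = n_shared / len(b) if len(b) else 0.0
    return f_a, f_b, (f_a + f_b) / 2


def jaccard(set_a: np.ndarray, set_b: np.ndarray) -> float:
    a = np.unique(np.asarray(set_a))
    b = np.unique(np.asarray(set_b))
    union = len(np.union1d(a, b))
    if union == 0:
        return 0.0
    return len(np.intersect1d(a, b, assume_unique=True)) / union


def random_pair_null(primary_sets: Sequence[np.ndarray]) -> np.ndarray:
    """Mean shared fractions over all unordered pairs of independent tumors.

    With ``n`` tumors this yields n(n-1)/2 values — the null distribution of
    sharing between unrelated pairs processed by the same pipeline.
    """
    n = len(primary_sets)
    if n < 2:
        raise ValueError("need at least two independent sets")
    sets = [np.unique(np.asarray(s)) for s in primary_sets]
    return np.array([shared_fraction(sets[i], sets[j])[2] for i, j in combinations(range(n), 2)])
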