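"""Core domain types for paired primary/recurrent tumor genome analysis.

Conventions used throughout the package:

* Coordinates are 1-based and end-inclusive (MAF/SEG convention).
* Chromosome names are canonicalised without a ``chr`` prefix; ``X``/``Y``
  are kept, the mitochondrion is excluded.
* A mutation is identified by ``(chrom, pos, ref, alt)`` after indel
  normalization (see :func:`recurrevol.io.normalize_variant`); sharing
  between samples means positional identity of that key.
* Sites absent from a sample's observation list are treated as
  unassayed (depth 0), not reference; force calling requires explicit
  per-sample depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_EFFECTS = ("nonsynonymous", "silent", "noncoding", "splice", "promoter")
VALID_ROLES = ("primary", "recurrent", "normal")

#: Mutation classes eligible for the clonality index: nonsynonymous SNVs and
#: indels only (silent / noncoding / promoter events are excluded).
CI_EFFECTS = ("nonsynonymous",)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant (SNV or indel) with annotation.

    ``pos``/``ref``/``alt`` are the normalized representation; for indels the
    empty side is written ``-``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # "SNV" | "indel"
    gene: str = ""
    effect: str = "noncoding"
    trinucleotide_context: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        is_snv = len(self.ref) == 1 == len(self.alt) and "-" not in (self.ref, self.alt)
        if (self.variant_class == "SNV") != is_snv:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )
        if self.effect not in VALID_EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Observation:
    """Read support for one mutation in one sample."""

    key: tuple[str, int, str, str]
    sample: str
    alt_reads: int
    ref_reads: int
    called: bool = True

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.alt_reads + self.ref_reads

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_reads / d if d > 0 else float("nan")


@dataclass(frozen=True)
class CnvSegment:
    """Copy-number segment (1-based, end-inclusive) for one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: Optional[int] = None
    minor_cn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample metadata: role, region, purity/ploidy, hepatic segments."""

    sample: str
    patient: str
    role: str
    purity: Optional[float] = None
    ploidy: Optional[float] = None
    region: str = ""
    hepatic_segments: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role != "normal":
            if self.purity is None or not (0 < self.purity <= 1):
                raise ValueError(f"tumor sample {self.sample} needs purity in (0, 1]")
            if self.ploidy is None or self.ploidy <= 0:
                raise ValueError(f"tumor sample {self.sample} needs positive ploidy")
        for s in self.hepatic_segments:
            if not 1 <= s <= 8:
                raise ValueError(f"hepatic segment {s} outside 1-8")


@dataclass
class CohortCatalog:
    """Background cohort mutation-frequency catalog.

    ``counts`` maps a mutation key to its occurrence count across the cohort;
    ``n_total`` is the total number of mutations found in the cohort (the
    denominator of the per-mutation population frequency).
    """

    counts: Mapping[tuple[str, int, str, str], int]
    n_total: int
    n_tumors: int = 0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("catalog n_total must be positive")
        if sum(self.counts.values()) > self.n_total:
            raise ValueError("sum of catalog counts exceeds n_total")


@dataclass
class PatientCase:
    """All inputs for one patient, in analysis-ready tabular form.

    ``mutations`` is a DataFrame with one row per distinct mutation key and
    columns ``chrom, pos, ref, alt, variant_class, gene, effect, context``.
    Read support is held as dense arrays over ``(mutation, sample)`` so the
    harmonization rules can be applied vectorised; ``samples`` fixes the
    column order of those arrays.
    """

    patient: str
    profiles: Sequence[SampleProfile]
    mutations: pd.DataFrame
    alt_reads: np.ndarray  # (n_mut, n_samples) int
    ref_reads: np.ndarray  # (n_mut, n_samples) int
    called: np.ndarray  # (n_mut, n_samples) bool
    segments: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    breakpoints: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    recurrence_months: Optional[float] = None

    def __post_init__(self) -> None:
        roles = [p.role for p in self.profiles]
        if roles.count("normal") != 1:
            raise ValueError("exactly one normal sample required per patient")
        if "primary" not in roles or "recurrent" not in roles:
            raise ValueError("need at least one primary and one recurrent sample")
        n_mut = len(self.mutations)
        n_s = len(self.profiles)
        for name, arr in (("alt_reads", self.alt_reads), ("ref_reads", self.ref_reads), ("called", self.called)):
            if arr.shape != (n_mut, n_s):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n_mut, n_s)}")
        if np.any(self.alt_reads < 0) or np.any(self.ref_reads < 0):
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return [p.sample for p in self.profiles]

    @property
    def tumor_samples(self) -> list[str]:
        return [p.sample for p in self.profiles if p.role != "normal"]

    @property
    def normal_sample(self) -> str:
        return next(p.sample for p in self.profiles if p.role == "normal")

    def profile(self, sample: str) -> SampleProfile:
        for p in self.profiles:
            if p.sample == sample:
                return p
        raise KeyError(sample)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def depth(self) -> np.ndarray:
        return self.alt_reads + self.ref_reads

    def keys(self) -> pd.Index:
        """Mutation keys as ``chrom:pos:ref:alt`` strings, aligned to rows."""
        m = self.mutations
        return pd.Index(
            m["chrom"].astype(str)
            + ":"
            + m["pos"].astype(str)
            + ":"
            + m["ref"].astype(str)
            + ":"
            + m["alt"].astype(str)
        )
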