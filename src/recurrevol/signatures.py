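"""Mutational spectra and signature-exposure refitting.

Substitution spectra use the pyrimidine-reference convention: the six
classes are C>A, C>G, C>T, T>A, T>C, T>G, and purine-reference SNVs are
reverse-complemented before counting. The 96-category resolution adds the
5' and 3' flanking bases (16 trinucleotide contexts per class, ordered
A, C, G, T on each flank).

Exposures are fitted by nonnegative least squares against a reference
signature matrix (96 categories x k signatures, columns summing to 1),
with signatures whose weight falls below a cutoff (default 6%) iteratively
zeroed and the remainder refitted — the standard refitting behaviour of
multiple-regression signature tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy import stats

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_CLASS_REF = "CCCTTT"
_CLASS_ALT = "AGTACG"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Labels of the 96 categories, grouped by class then 5' then 3' base.
CATEGORY_LABELS = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUB_CLASSES
    for five in _BASES
    for three in _BASES
)


@dataclass
class Spectrum:
    """Six-class substitution counts with an optional 96-context vector."""

    counts6: pd.Series
    counts96: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.counts6 < 0).any():
            raise ValueError("negative spectrum counts")
        if self.counts96 is not None:
            marg = self.counts96.reshape(6, 16).sum(axis=1)
            if not np.array_equal(marg, self.counts6.to_numpy()):
                raise ValueError("96-vector does not marginalize to the 6-class counts")


@dataclass
class SignatureExposure:
    """Mixture weights over reference signatures plus the fit residual."""

    weights: pd.Series
    rss: float
    n_mutations: int = 0
    low_confidence: bool = False


def category_index(ref: str, alt: str, context: str) -> int:
    """96-category index for a pyrimidine- or purine-stranded SNV."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    cls = SUB_CLASSES.index(f"{ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} inconsistent with ref {ref}")
    return cls * 16 + _BASES.index(context[0]) * 4 + _BASES.index(context[2])


def category_to_alleles(cats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode 96-category indices to (ref, alt, context) arrays."""
    cats = np.asarray(cats, dtype=np.int64)
    cls, rem = cats // 16, cats % 16
    five, three = rem // 4, rem % 4
    ref = np.array(list(_CLASS_REF), dtype=object)[cls]
    alt = np.array(list(_CLASS_ALT), dtype=object)[cls]
    b = np.array(list(_BASES), dtype=object)
    ctx = b[five] + ref + b[three]
    return ref, alt, ctx


def complement_alleles(bases: np.ndarray) -> np.ndarray:
    return np.array([_COMPLEMENT[b] for b in bases], dtype=object)


def reverse_complement_contexts(contexts: np.ndarray) -> np.ndarray:
    return np.array(
        ["".join(_COMPLEMENT[b] for b in reversed(c)) for c in contexts], dtype=object
    )


def spectrum(mutations: pd.DataFrame, with_context: bool = False) -> Spectrum:
    """Substitution spectrum of a mutation table (SNVs only, indels skipped).

    With ``with_context`` the 96-vector is computed too, which requires a
    3-letter ``context`` column on every SNV row.
    """
    snv = mutations[mutations["variant_class"] == "SNV"] if "variant_class" in mutations else mutations
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_i = snv["ref"].astype(str).str.upper().map(base_idx).to_numpy()
    alt_i = snv["alt"].astype(str).str.upper().map(base_idx).to_numpy()
    purine = (ref_i == 0) | (ref_i == 2)
    ref_c = np.where(purine, 3 - ref_i, ref_i)
    alt_c = np.where(purine, 3 - alt_i, alt_i)
    # pyrimidine ref is C (1) or T (3); class index within SUB_CLASSES
    pair_to_class = {(1, 0): 0, (1, 2): 1, (1, 3): 2, (3, 0): 3, (3, 1): 4, (3, 2): 5}
    cls = np.array([pair_to_class[(r, a)] for r, a in zip(ref_c, alt_c)], dtype=np.int64)
    counts6 = np.bincount(cls, minlength=6)
    counts96 = None
    if with_context:
        ctx = snv["context"].astype(str).str.upper() if "context" in snv else pd.Series("", index=snv.index)
        if (ctx.str.len() != 3).any():
            raise ValueError("96-context spectrum requires a trinucleotide context per SNV")
        five = ctx.str[0].map(base_idx).to_numpy()
        three = ctx.str[2].map(base_idx).to_numpy()
        # purine-stranded rows: context is reverse-complemented
        five_p, three_p = 3 - three, 3 - five
        five = np.where(purine, five_p, five)
        three = np.where(purine, three_p, three)
        counts96 = np.bincount(cls * 16 + five * 4 + three, minlength=96)
    return Spectrum(counts6=pd.Series(counts6, index=list(SUB_CLASSES)), counts96=counts96)


def synthetic_reference_signatures(n_signatures: int = 30) -> pd.DataFrame:
    """Synthetic 30-signature reference matrix (96 categories x signatures).

    This is a deterministically generated *synthetic* stand-in for a
    curated reference catalog, with the etiologically meaningful shapes the
    analyses rely on: Signature.1 (CpG C>T, spontaneous deamination),
    Signature.4 and Signature.24 (C>A, tobacco / aflatoxin), Signature.5
    (flat, aging), Signature.12 and Signature.16 (T>C), and Signature.22
    (dominant T>A, aristolochic acid). The remaining columns are random
    sparse probability vectors. Column labels follow the ``Signature.k``
    convention so externally supplied matrices with matching labels drop in.
    """
    rng = np.random.default_rng(20_220_126)
    cols = {}
    special = {
        1: (2, 0.75, "threeG"),  # C>T at NpCpG
        4: (0, 0.70, None),      # C>A
        12: (4, 0.60, None),     # T>C
        16: (4, 0.60, "fiveA"),  # T>C, 5'A emphasis
        22: (3, 0.80, None),     # T>A dominant
        24: (0, 0.65, "fiveG"),  # C>A, distinct context profile
    }
    for j in range(1, n_signatures + 1):
        base = rng.dirichlet(np.full(96, 0.25))
        if j == 5:  # flat aging-like signature
            col = 0.6 * np.full(96, 1 / 96) + 0.4 * rng.dirichlet(np.full(96, 5.0))
        elif j in special:
            cls, mass, flavor = special[j]
            ctx_w = rng.dirichlet(np.ones(16))
            if flavor == "threeG":
                ctx_w = np.where(np.arange(16) % 4 == 2, ctx_w + 0.5, ctx_w * 0.1)
            elif flavor == "fiveA":
                ctx_w = np.where(np.arange(16) // 4 == 0, ctx_w + 0.5, ctx_w * 0.1)
            elif flavor == "fiveG":
                ctx_w = np.where(np.arange(16) // 4 == 2, ctx_w + 0.5, ctx_w * 0.1)
            ctx_w = ctx_w / ctx_w.sum()
            col = (1 - mass) * base
            col[cls * 16 : (cls + 1) * 16] += mass * ctx_w
        else:
            col = base
        cols[f"Signature.{j}"] = col / col.sum()
    return pd.DataFrame(cols, index=list(CATEGORY_LABELS))


def write_reference_signatures(path, matrix: Optional[pd.DataFrame] = None) -> None:
    """Export the synthetic reference matrix as TSV (96 rows x k signatures)."""
    (matrix if matrix is not None else synthetic_reference_signatures()).to_csv(path, sep="\t")


def read_signature_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 category rows, got {m.shape[0]}")
    if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must sum to 1")
    return m


def refit_exposures(
    spectrum96: np.ndarray,
    signature_matrix: pd.DataFrame,
    cutoff: float = 0.06,
) -> SignatureExposure:
    """Nonnegative-least-squares exposure refit with iterative thresholding.

    The normalized 96-category spectrum is regressed on the reference
    columns; any signature whose normalized weight falls below ``cutoff`` is
    removed and the remainder refitted until all retained weights clear the
    cutoff. Final weights are renormalized to sum 1, with excluded
    signatures reported as exactly 0.
    """
    x = np.asarray(spectrum96, dtype=float)
    if x.shape != (signature_matrix.shape[0],):
        raise ValueError(
            f"spectrum has {x.shape} categories, matrix has {signature_matrix.shape[0]}"
        )
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot refit a zero spectrum")
    x = x / total
    names = list(signature_matrix.columns)
    active = list(range(len(names)))
    A_full = signature_matrix.to_numpy()
    w_active = None
    while True:
        A = A_full[:, active]
        w, _ = nnls(A, x)
        s = w.sum()
        w_norm = w / s if s > 0 else w
        below = [i for i, v in enumerate(w_norm) if v < cutoff]
        if not below or len(below) == len(active):
            w_active = w_norm if s > 0 else np.zeros(len(active))
            break
        active = [a for i, a in enumerate(active) if w_norm[i] >= cutoff]
    weights = pd.Series(0.0, index=names)
    for i, a in enumerate(active):
        weights.iloc[a] = w_active[i]
    if weights.sum() > 0:
        weights = weights / weights.sum()
    resid = x - A_full @ weights.to_numpy()
    rss = float((resid**2).sum())
    return SignatureExposure(weights=weights, rss=rss, n_mutations=int(total))


def hypermutation_flag(n_mutations: int, genome_mb: float = 2800.0, threshold: float = 9.0) -> bool:
    """True when the genome-wide mutation rate strictly exceeds ``threshold``/Mb."""
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be >= 0")
    return n_mutations / genome_mb > threshold


def category_exposures(
    mutations_by_category: Mapping[str, pd.DataFrame],
    signature_matrix: pd.DataFrame,
    cutoff: float = 0.06,
    low_confidence_below: int = 50,
) -> dict[str, SignatureExposure]:
    """Refit exposures for each mutation-cluster category's spectrum.

    Categories without SNVs are skipped with a warning-style omission;
    categories with fewer than ``low_confidence_below`` mutations are
    flagged low-confidence.
    """
    out: dict[str, SignatureExposure] = {}
    for cat, muts in mutations_by_category.items():
        if len(muts) == 0:
            continue
        spec = spectrum(muts, with_context=True)
        if spec.counts96 is None or spec.counts96.sum() == 0:
            continue
        exp = refit_exposures(spec.counts96, signature_matrix, cutoff)
        exp.n_mutations = int(spec.counts96.sum())
        exp.low_confidence = exp.n_mutations < low_confidence_below
        out[cat] = exp
    return out


def compare_exposures(
    patient_exposures: Sequence[Mapping[str, SignatureExposure]],
    category_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Paired t statistics per signature for each category pair across patients.

    Patients lacking either category of a pair are skipped for that pair;
    with fewer than two informative patients the test is not computed and
    only descriptive means are reported (t and p set to NaN).
    """
    rows = []
    for cat_a, cat_b in category_pairs:
        pairs = [
            (pe[cat_a].weights, pe[cat_b].weights)
            for pe in patient_exposures
            if cat_a in pe and cat_b in pe
        ]
        if not pairs:
            continue
        A = pd.DataFrame([a for a, _ in pairs])
        B = pd.DataFrame([b for _, b in pairs])
        for sig in A.columns:
            a, b = A[sig].to_numpy(), B[sig].to_numpy()
            if len(pairs) >= 2 and not np.allclose(a, b):
                t, p = stats.ttest_rel(a, b)
            elif len(pairs) >= 2:
                t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
            rows.append(
                {
                    "category_a": cat_a,
                    "category_b": cat_b,
                    "signature": sig,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "t": float(t) if t == t else np.nan,
                    "p": float(p) if p == p else np.nan,
                    "n": len(pairs),
                }
            )
    return pd.DataFrame(rows)
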