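"""End-to-end per-case and per-cohort orchestration.

``run_case`` chains the stages in the order the analysis requires:
harmonization (filters, CNV drop, force calling) -> relatedness (clonality
index vs a calibrated or supplied cutoff, recurrence location, breakpoint
sharing, WGD) -> subclonal inference (CCF clustering, cluster filter,
categories) -> evolution (pigeonhole architecture, phylogeny, drivers,
heterogeneity, seeding) -> per-category signature exposures.

``run_cohort`` aggregates case results into the cohort-level tables:
pattern x location and WGD x pattern contingency (chi-square without
continuity correction when all expected counts are >= 5, else Fisher's
exact test), driver-timing fractions, and paired signature-exposure
comparisons between evolutionary stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ccf as ccf_mod
from . import evolution, harmonize, relatedness, signatures
from .io import tree_to_nested, write_case_report
from .types import CI_EFFECTS, CohortCatalog, PatientCase


@dataclass
class PipelineConfig:
    cutoff: Optional[float] = None  # CI cutoff; None -> calibrate
    calibration_repeats: int = 100
    eps: float = 0.05
    clonal_thr: float = 0.8
    presence_thr: float = 0.05
    min_cluster_fraction: float = 0.005
    signature_cutoff: float = 0.06
    max_k: int = 8
    seed: int = 0

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


@dataclass
class CaseResult:
    patient: str
    pattern: str
    ci: float
    cutoff: float
    n_shared_nonsyn: int
    hsi: int
    location: str
    sharing: dict
    wgd: dict
    shared_sv: int
    shared_viral: int
    clusters: pd.DataFrame
    categories: dict
    scheme: str
    trees: dict
    heterogeneity: Optional[evolution.HeterogeneityResult]
    seeding: Optional[dict]
    drivers: list
    exposures: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "pattern": self.pattern,
            "ci": self.ci,
            "cutoff": self.cutoff,
            "n_shared_nonsyn": self.n_shared_nonsyn,
            "hsi": self.hsi,
            "location": self.location,
            "sharing": self.sharing,
            "wgd": self.wgd,
            "shared_sv": self.shared_sv,
            "shared_viral": self.shared_viral,
            "scheme": self.scheme,
            "categories": self.categories,
            "trees": self.trees,
            "heterogeneity": None
            if self.heterogeneity is None
            else {
                "spatial_mean": self.heterogeneity.spatial_mean,
                "temporal_mean": self.heterogeneity.temporal_mean,
            },
            "seeding": self.seeding,
            "provenance": self.provenance,
            "tables": {
                "clusters": self.clusters.to_dict(orient="list"),
                "relatedness": {
                    "patient": [self.patient],
                    "ci": [self.ci],
                    "cutoff": [self.cutoff],
                    "pattern": [self.pattern],
                    "f_primary": [self.sharing["f_primary"]],
                    "f_recurrent": [self.sharing["f_recurrent"]],
                    "f_mean": [self.sharing["f_mean"]],
                    "jaccard": [self.sharing["jaccard"]],
                    "hsi": [self.hsi],
                    "location": [self.location],
                    "shared_sv": [self.shared_sv],
                    "shared_viral": [self.shared_viral],
                },
                "sharing": {k: [v] for k, v in self.sharing.items()},
                "exposures": _exposure_table(self.patient, self.exposures),
                "categories": {
                    "cluster": list(self.categories.keys()),
                    "category": list(self.categories.values()),
                },
            },
        }


def _exposure_table(patient: str, exposures: Mapping[str, signatures.SignatureExposure]) -> dict:
    rows = {"patient": [], "category": [], "signature": [], "weight": []}
    for cat, exp in exposures.items():
        for sig, w in exp.weights.items():
            if w > 0:
                rows["patient"].append(patient)
                rows["category"].append(cat)
                rows["signature"].append(sig)
                rows["weight"].append(float(w))
    return rows


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def case_clonality(
    case: PatientCase,
    catalog: CohortCatalog,
    cutoff: float,
    harmonized: Optional[harmonize.HarmonizedCase] = None,
) -> dict:
    """Harmonize a case and classify its recurrence pattern by CI.

    Returns the harmonized case, the primary/recurrent union row sets, the
    sharing statistics (before and after force calling), the clonality
    index over shared nonsynonymous keys and the resulting pattern call.
    """
    hc = harmonized if harmonized is not None else harmonize.harmonize_case(case)
    sets = hc.final_sets()
    roles = {p.sample: p.role for p in case.profiles}
    primary_rows = _union([sets[s] for s in hc.tumor_samples if roles[s] == "primary"])
    recurrent_rows = _union([sets[s] for s in hc.tumor_samples if roles[s] == "recurrent"])
    f_p, f_r, f_mean = harmonize.shared_fraction(primary_rows, recurrent_rows)
    jac = harmonize.jaccard(primary_rows, recurrent_rows)
    called_only = hc.status == harmonize.CALLED
    pre_p = _union(
        [np.flatnonzero(called_only[:, j]) for j, s in enumerate(hc.tumor_samples) if roles[s] == "primary"]
    )
    pre_r = _union(
        [np.flatnonzero(called_only[:, j]) for j, s in enumerate(hc.tumor_samples) if roles[s] == "recurrent"]
    )
    f_mean_before = harmonize.shared_fraction(pre_p, pre_r)[2]
    shared = np.intersect1d(primary_rows, recurrent_rows, assume_unique=True)
    eff = case.mutations["effect"].to_numpy(dtype=object)
    shared_nonsyn = shared[np.isin(eff[shared], list(CI_EFFECTS))]
    key_frame = case.mutations.iloc[shared_nonsyn]
    keys = [(r.chrom, int(r.pos), r.ref, r.alt) for r in key_frame.itertuples(index=False)]
    clon = relatedness.clonality_index(keys, catalog)
    clon.cutoff = cutoff
    clon.pattern = relatedness.classify_recurrence(clon.ci, cutoff)
    return {
        "harmonized": hc,
        "primary_rows": primary_rows,
        "recurrent_rows": recurrent_rows,
        "shared_rows": shared,
        "clonality": clon,
        "pattern": clon.pattern,
        "sharing": {
            "f_primary": f_p,
            "f_recurrent": f_r,
            "f_mean": f_mean,
            "f_mean_before_force_calling": f_mean_before,
            "jaccard": jac,
            "n_shared": int(len(shared)),
        },
    }


def run_case(
    case: PatientCase,
    catalog: Optional[CohortCatalog] = None,
    config: Optional[PipelineConfig] = None,
    calibration_sets: Optional[Sequence[np.ndarray]] = None,
    signature_matrix: Optional[pd.DataFrame] = None,
    out_dir=None,
) -> CaseResult:
    """Run the full per-case analysis; see the module docstring for stages."""
    cfg = config or PipelineConfig()
    if cfg.cutoff is None and calibration_sets is None:
        raise PipelineError("config", "either a CI cutoff or calibration inputs are required")
    if catalog is None:
        raise PipelineError("config", "a background mutation catalog is required")
    S = signature_matrix if signature_matrix is not None else signatures.synthetic_reference_signatures()

    # -- harmonization + relatedness --------------------------------------
    try:
        cutoff = cfg.cutoff
        if cutoff is None:
            cal = relatedness.calibrate_ci_cutoff(
                calibration_sets, repeats=cfg.calibration_repeats, seed=cfg.seed
            )
            cutoff = cal.cutoff
        clonality = case_clonality(case, catalog, cutoff)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("harmonization", str(e)) from e
    hc = clonality["harmonized"]
    sets = hc.final_sets()
    roles = {p.sample: p.role for p in case.profiles}
    primary_rows = clonality["primary_rows"]
    recurrent_rows = clonality["recurrent_rows"]
    shared = clonality["shared_rows"]
    clon = clonality["clonality"]
    pattern = clonality["pattern"]

    try:
        prim_segs = set().union(*(p.hepatic_segments for p in case.profiles if p.role == "primary"))
        rec_segs = set().union(*(p.hepatic_segments for p in case.profiles if p.role == "recurrent"))
        hsi = relatedness.hepatic_segment_interval(prim_segs, rec_segs)
        location = relatedness.classify_location(hsi).location
        wgd = {
            p.sample: relatedness.call_wgd(p.ploidy)
            for p in case.profiles
            if p.role != "normal"
        }
        shared_sv, shared_viral = _breakpoint_sharing(case, roles)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("relatedness", str(e)) from e

    # -- subclonal inference -----------------------------------------------
    try:
        clusters = ccf_mod.cluster_mutations(hc, seed=cfg.seed, max_k=cfg.max_k)
        total = len(hc.union_rows())
        clusters = ccf_mod.filter_clusters(clusters, total, cfg.min_cluster_fraction)
        n_primary_regions = sum(1 for r in roles.values() if r == "primary")
        n_recurrent_regions = sum(1 for r in roles.values() if r == "recurrent")
        multi_region = n_primary_regions > 1 or n_recurrent_regions > 1
        scheme = "multi_region" if multi_region else pattern
        assignment = ccf_mod.classify_cluster_categories(
            clusters, roles, scheme, cfg.clonal_thr, cfg.presence_thr
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("subclonal_inference", str(e)) from e

    # -- evolution ----------------------------------------------------------
    try:
        primary_total = max(len(primary_rows), 1)
        trees = {}
        if scheme == "de_novo":
            for side, prefix in (("primary", "primary"), ("recurrent", "recurrence")):
                side_clusters = [
                    c for c in clusters
                    if assignment.categories.get(c.cluster_id, "").startswith(prefix)
                ]
                if side_clusters:
                    t = evolution.build_subclonal_architecture(side_clusters, cfg.eps)
                    t = evolution.build_phylogeny(t, primary_total)
                    trees[side] = _tree_dict(t)
        else:
            if clusters:
                t = evolution.build_subclonal_architecture(clusters, cfg.eps)
                t = evolution.build_phylogeny(t, primary_total)
                trees["joint"] = _tree_dict(t)
        drivers = evolution.label_drivers(case, clusters, assignment)
        region_sets = {s: sets[s] for s in hc.tumor_samples}
        het = evolution.spatial_temporal_ith(region_sets, roles)
        seeding = None
        if n_recurrent_regions >= 2:
            seeding = evolution.detect_polyclonal_seeding(
                clusters, assignment, roles, cfg.presence_thr, cfg.clonal_thr
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("evolution", str(e)) from e

    # -- signatures ----------------------------------------------------------
    try:
        by_cat: dict[str, pd.DataFrame] = {}
        for c in clusters:
            cat = assignment.categories.get(c.cluster_id)
            if cat is None:
                continue
            frame = case.mutations.iloc[c.member_rows]
            snv = frame[frame["variant_class"] == "SNV"]
            by_cat[cat] = pd.concat([by_cat[cat], snv]) if cat in by_cat else snv
        exposures = signatures.category_exposures(by_cat, S, cfg.signature_cutoff)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("signatures", str(e)) from e

    cluster_table = pd.DataFrame(
        [
            {"cluster": c.cluster_id, "sample": s, "ccf": float(c.ccf[s]), "size": c.size}
            for c in clusters
            for s in c.ccf.index
        ]
    )
    result = CaseResult(
        patient=case.patient,
        pattern=pattern,
        ci=clon.ci,
        cutoff=float(cutoff),
        n_shared_nonsyn=clon.n_shared,
        hsi=hsi,
        location=location,
        sharing=clonality["sharing"],
        wgd=wgd,
        shared_sv=shared_sv,
        shared_viral=shared_viral,
        clusters=cluster_table,
        categories=dict(assignment.categories),
        scheme=scheme,
        trees=trees,
        heterogeneity=het,
        seeding=seeding,
        drivers=drivers,
        exposures=exposures,
        provenance={"seed": cfg.seed, "config_hash": cfg.hash()},
    )
    if out_dir is not None:
        write_case_report(result.to_dict(), out_dir)
        keys = case.keys()
        rows = []
        for j, s in enumerate(hc.tumor_samples):
            cj = case.sample_index(s)
            nonabsent = hc.status[:, j] != harmonize.ABSENT
            rows.append(
                pd.DataFrame(
                    {
                        "key": keys[nonabsent],
                        "sample": s,
                        "status": [harmonize.STATUS_NAMES[v] for v in hc.status[nonabsent, j]],
                        "alt_reads": case.alt_reads[nonabsent, cj],
                        "ref_reads": case.ref_reads[nonabsent, cj],
                    }
                )
            )
        from pathlib import Path

        pd.concat(rows, ignore_index=True).to_csv(
            Path(out_dir) / "harmonized_mutations.tsv", sep="\t", index=False
        )
    return result


def _union(arrays: Sequence[np.ndarray]) -> np.ndarray:
    if not arrays:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate(arrays))


def _breakpoint_sharing(case: PatientCase, roles: Mapping[str, str]) -> tuple[int, int]:
    prim = [s for s, r in roles.items() if r == "primary" and s in (case.breakpoints or {})]
    rec = [s for s, r in roles.items() if r == "recurrent" and s in (case.breakpoints or {})]
    if not prim or not rec:
        return 0, 0
    a = pd.concat([case.breakpoints[s] for s in prim], ignore_index=True)
    b = pd.concat([case.breakpoints[s] for s in rec], ignore_index=True)
    sv = relatedness.shared_breakpoints(a, b, bp_type="SV")
    viral = relatedness.shared_breakpoints(a, b, bp_type="HBV")
    return sv, viral


def _tree_dict(tree: evolution.CloneTree) -> dict:
    payload = {
        node: {
            "n_mutations": int(tree.sizes.get(node, 0)),
            "relative_length": (tree.sizes.get(node, 0) / tree.scale) if tree.scale else None,
            "ccf": {s: float(tree.ccf.at[node, s]) for s in tree.ccf.columns},
        }
        for node in tree.parents
    }
    return tree_to_nested(tree.parents, payload)


# ---------------------------------------------------------------------------
# cohort aggregation


def contingency_test(table: pd.DataFrame) -> dict:
    """Chi-square without continuity correction when all expected counts are
    >= 5, else Fisher's exact test (2x2 only for Fisher)."""
    obs = table.to_numpy(dtype=float)
    if obs.sum() == 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        return {"test": "none", "statistic": np.nan, "p": np.nan}
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected >= 5).all():
        return {"test": "chi2", "statistic": float(chi2), "p": float(p)}
    if obs.shape == (2, 2):
        odds, p = stats.fisher_exact(obs)
        return {"test": "fisher", "statistic": float(odds), "p": float(p)}
    return {"test": "chi2", "statistic": float(chi2), "p": float(p)}


def run_cohort(results: Sequence[CaseResult]) -> dict:
    """Aggregate case results into cohort-level summary tables and tests."""
    if not results:
        raise ValueError("empty cohort")
    results = sorted(results, key=lambda r: r.patient)
    frame = pd.DataFrame(
        {
            "patient": [r.patient for r in results],
            "pattern": [r.pattern for r in results],
            "location": [r.location for r in results],
            "wgd_recurrent": [
                any(v for s, v in r.wgd.items() if s.split("_")[-1].startswith("R"))
                for r in results
            ],
        }
    )
    out: dict = {"cases": frame}
    pattern_location = pd.crosstab(frame["pattern"], frame["location"])
    out["pattern_by_location"] = pattern_location
    out["pattern_by_location_test"] = (
        contingency_test(pattern_location) if len(results) > 1 else {"test": "none"}
    )
    wgd_pattern = pd.crosstab(frame["pattern"], frame["wgd_recurrent"])
    out["wgd_by_pattern"] = wgd_pattern
    out["wgd_by_pattern_test"] = (
        contingency_test(wgd_pattern) if len(results) > 1 else {"test": "none"}
    )
    out["driver_timing"] = evolution.driver_timing_summary([r.drivers for r in results])
    anc = [r.exposures for r in results if r.pattern == "ancestral" and r.scheme == "ancestral"]
    if anc:
        pairs = [
            ("trunk_clone", "primary_branch"),
            ("trunk_clone", "recurrence_branch"),
            ("trunk_subclone", "primary_branch"),
            ("trunk_subclone", "recurrence_branch"),
        ]
        out["exposure_comparisons"] = signatures.compare_exposures(anc, pairs)
    return out
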