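"""Readers and writers for the tabular formats the pipeline touches.

Formats:

* mutation tables — MAF-like TSV, one row per (mutation, sample) with read
  support (columns ``chrom pos ref alt variant_class gene effect context
  sample alt_reads ref_reads called``);
* copy-number segments — SEG-like TSV (``sample chrom start end total_cn
  [major_cn minor_cn]``), 1-based end-inclusive;
* cohort catalogs — MAF-like TSV reduced to occurrence counts;
* case manifests — YAML/JSON naming the input files and per-sample metadata;
* case reports — JSON summary + TSV tables + Newick tree.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .types import (
    CnvSegment,
    CohortCatalog,
    MutationRecord,
    Observation,
    PatientCase,
    SampleProfile,
)

MUTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene",
    "effect",
    "context",
    "sample",
    "alt_reads",
    "ref_reads",
    "called",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome name: no ``chr`` prefix, X/Y kept."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an allele pair to a canonical representation.

    Shared suffix then shared prefix bases are trimmed and the position is
    anchored at the first differing base; an empty allele is written ``-``.
    This unifies the common indel dialects, e.g. ``(100, "CA", "C")`` and
    ``(101, "A", "-")`` both normalize to ``(101, "A", "-")``.

    Note: without a reference sequence, repeats cannot be shifted further
    left; this trim-based canonical form is the package's convention.
    """
    ref = "" if ref in ("-", ".", "") else str(ref).upper()
    alt = "" if alt in ("-", ".", "") else str(alt).upper()
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref and alt and ref[0] == alt[0] and ref != alt:
        # e.g. ("CA", "C") -> deletion of "A" anchored one base right
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"ref and alt identical after normalization at pos {pos}")
    return pos, ref or "-", alt or "-"


def _key_strings(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def read_mutation_table(path: str | Path) -> tuple[list[MutationRecord], list[Observation]]:
    """Read a MAF-like mutation TSV into records and observations.

    Keys are normalized (chromosome canonicalised, indel alleles trimmed);
    duplicate (key, sample) rows are rejected.
    """
    df = read_mutation_frame(path)
    records: dict[tuple, MutationRecord] = {}
    observations: list[Observation] = []
    for row in df.itertuples(index=False):
        rec = MutationRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            variant_class=row.variant_class,
            gene=row.gene,
            effect=row.effect,
            trinucleotide_context=row.context,
        )
        records.setdefault(rec.key, rec)
        observations.append(
            Observation(
                key=rec.key,
                sample=row.sample,
                alt_reads=int(row.alt_reads),
                ref_reads=int(row.ref_reads),
                called=bool(row.called),
            )
        )
    return list(records.values()), observations


def read_mutation_frame(path: str | Path) -> pd.DataFrame:
    """Read and normalize a mutation table as a DataFrame (fast path)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if (df["alt_reads"] < 0).any() or (df["ref_reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["gene"] = df["gene"].fillna("")
    df["context"] = df["context"].fillna("")
    norm = [normalize_variant(p, r, a) for p, r, a in zip(df["pos"], df["ref"], df["alt"])]
    df[["pos", "ref", "alt"]] = pd.DataFrame(norm, index=df.index)
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt", "sample"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate (mutation, sample) row at "
            f"{first.chrom}:{first.pos} {first.ref}>{first.alt} in {first['sample']}"
        )
    df["called"] = df["called"].astype(int).astype(bool)
    return df


def write_mutation_frame(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["called"] = out["called"].astype(int)
    out[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cnv_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like TSV; validates coordinates and non-overlap."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for c in ("start", "end", "total_cn"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise FormatError(f"{path}: non-numeric values in column {c}")
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: segment with start > end")
    if (df["total_cn"] < 0).any():
        raise ValueError(f"{path}: negative total_cn")
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].values[1:] <= g["end"].values[:-1]).any():
            raise ValueError(f"{path}: overlapping segments for {sample} chr{chrom}")
    return df


def segments_to_frame(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "total_cn": s.total_cn,
            }
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )


def local_copy_number(
    segments: pd.DataFrame,
    chrom: str,
    pos: int,
    fallback: int = 2,
) -> int:
    """Total copy number of the unique segment covering ``(chrom, pos)``.

    Coordinates are 1-based end-inclusive on both sides; positions outside
    every segment return ``fallback`` (round(ploidy) if available upstream,
    else 2).
    """
    chrom = normalize_chrom(chrom)
    hit = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] <= pos)
        & (segments["end"] >= pos)
    ]
    if len(hit) > 1:
        raise ValueError(f"overlapping segments cover {chrom}:{pos}")
    if len(hit) == 0:
        return int(fallback)
    return int(hit["total_cn"].iloc[0])


def local_copy_number_batch(
    segments: pd.DataFrame,
    chroms: np.ndarray,
    positions: np.ndarray,
    fallback: int = 2,
) -> np.ndarray:
    """Vectorised :func:`local_copy_number` over many loci of one sample."""
    out = np.full(len(positions), int(fallback), dtype=np.int64)
    if len(segments) == 0:
        return out
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    for chrom, grp in segments.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        g = grp.sort_values("start")
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        cns = g["total_cn"].to_numpy(np.int64)
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        covered = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        vals = out[mask]
        vals[covered] = cns[idx[covered]]
        out[mask] = vals
    return out


def read_cohort_catalog(path: str | Path) -> CohortCatalog:
    """Build a mutation-frequency catalog from a MAF-like TSV.

    Each row is one mutation occurrence in one cohort tumor; identical
    normalized keys are counted. Requires columns ``chrom pos ref alt``
    and optionally ``sample`` (to count tumors).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for c in ("chrom", "pos", "ref", "alt"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {c}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    norm = [normalize_variant(p, r, a) for p, r, a in zip(df["pos"], df["ref"], df["alt"])]
    df[["pos", "ref", "alt"]] = pd.DataFrame(norm, index=df.index)
    keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    n_tumors = df["sample"].nunique() if "sample" in df.columns else 0
    return CohortCatalog(counts=counts, n_total=len(df), n_tumors=n_tumors)


def write_cohort_catalog(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> PatientCase:
    """Read a case manifest (YAML or JSON) and load the files it names.

    The manifest holds the patient id, recurrence time, per-sample profiles
    (role, region, purity, ploidy, hepatic segments) and paths — relative to
    the manifest — of the mutation table, segment table and optional
    breakpoint tables.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    profiles = []
    for s in doc["samples"]:
        profiles.append(
            SampleProfile(
                sample=s["id"],
                patient=doc["patient"],
                role=s["role"],
                purity=s.get("purity"),
                ploidy=s.get("ploidy"),
                region=s.get("region", ""),
                hepatic_segments=frozenset(s.get("hepatic_segments", [])),
            )
        )
    mut_path = base / doc["mutation_table"]
    if not mut_path.exists():
        raise FileNotFoundError(f"manifest references missing file {mut_path}")
    muts = read_mutation_frame(mut_path)
    declared = {p.sample for p in profiles}
    seen = set(muts["sample"].unique())
    if not seen <= declared:
        raise FormatError(f"{mut_path}: observations for undeclared samples {seen - declared}")

    segments: dict[str, pd.DataFrame] = {}
    if doc.get("cnv_segments"):
        seg_path = base / doc["cnv_segments"]
        if not seg_path.exists():
            raise FileNotFoundError(f"manifest references missing file {seg_path}")
        seg = read_cnv_segments(seg_path)
        if not set(seg["sample"].unique()) <= declared:
            raise FormatError(f"{seg_path}: segments for undeclared samples")
        segments = {s: g.reset_index(drop=True) for s, g in seg.groupby("sample")}

    breakpoints: dict[str, pd.DataFrame] = {}
    if doc.get("breakpoints"):
        bp_path = base / doc["breakpoints"]
        if not bp_path.exists():
            raise FileNotFoundError(f"manifest references missing file {bp_path}")
        bp = pd.read_csv(bp_path, sep="\t", dtype={"chrom1": str, "chrom2": str})
        breakpoints = {s: g.reset_index(drop=True) for s, g in bp.groupby("sample")}

    return case_from_frames(
        patient=doc["patient"],
        profiles=profiles,
        mutation_frame=muts,
        segments=segments,
        breakpoints=breakpoints,
        recurrence_months=doc.get("recurrence_months"),
    )


def case_from_frames(
    patient: str,
    profiles: list[SampleProfile],
    mutation_frame: pd.DataFrame,
    segments: Optional[Mapping[str, pd.DataFrame]] = None,
    breakpoints: Optional[Mapping[str, pd.DataFrame]] = None,
    recurrence_months: Optional[float] = None,
) -> PatientCase:
    """Assemble a :class:`PatientCase` from a long-format mutation frame."""
    samples = [p.sample for p in profiles]
    key_cols = ["chrom", "pos", "ref", "alt"]
    anno_cols = key_cols + ["variant_class", "gene", "effect", "context"]
    muts = (
        mutation_frame.sort_values(key_cols)
        .drop_duplicates(subset=key_cols)[anno_cols]
        .reset_index(drop=True)
    )
    key_index = pd.MultiIndex.from_frame(muts[key_cols])
    row_of = pd.Series(np.arange(len(muts)), index=key_index)
    n_mut, n_s = len(muts), len(samples)
    alt = np.zeros((n_mut, n_s), dtype=np.int64)
    ref = np.zeros((n_mut, n_s), dtype=np.int64)
    called = np.zeros((n_mut, n_s), dtype=bool)
    for j, sample in enumerate(samples):
        sub = mutation_frame[mutation_frame["sample"] == sample]
        if len(sub) == 0:
            continue
        rows = row_of.loc[pd.MultiIndex.from_frame(sub[key_cols])].to_numpy()
        alt[rows, j] = sub["alt_reads"].to_numpy()
        ref[rows, j] = sub["ref_reads"].to_numpy()
        called[rows, j] = sub["called"].to_numpy()
    return PatientCase(
        patient=patient,
        profiles=profiles,
        mutations=muts,
        alt_reads=alt,
        ref_reads=ref,
        called=called,
        segments=dict(segments or {}),
        breakpoints=dict(breakpoints or {}),
        recurrence_months=recurrence_months,
    )


def tree_to_newick(parents: Mapping[str, Optional[str]], lengths: Mapping[str, float]) -> str:
    """Serialize a clone tree to Newick with cluster ids as labels.

    ``parents`` maps node id -> parent id (root maps to None); ``lengths``
    carries the branch length (mutation count or relative length) per node.
    """
    children: dict[Optional[str], list[str]] = {}
    for node, parent in parents.items():
        children.setdefault(parent, []).append(node)
    roots = children.get(None, [])
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {roots}")

    def render(node: str) -> str:
        kids = sorted(children.get(node, []))
        label = f"{node}:{lengths.get(node, 0):g}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(roots[0]) + ";"


def tree_to_nested(parents: Mapping[str, Optional[str]], payload: Mapping[str, dict]) -> dict:
    """Clone tree as nested JSON-serialisable dicts."""
    children: dict[Optional[str], list[str]] = {}
    for node, parent in parents.items():
        children.setdefault(parent, []).append(node)
    (root,) = children[None]

    def build(node: str) -> dict:
        return {
            "id": node,
            **payload.get(node, {}),
            "children": [build(k) for k in sorted(children.get(node, []))],
        }

    return build(root)


def nested_to_parents(tree: dict) -> dict[str, Optional[str]]:
    parents: dict[str, Optional[str]] = {}

    def walk(node: dict, parent: Optional[str]) -> None:
        parents[node["id"]] = parent
        for child in node.get("children", []):
            walk(child, node["id"])

    walk(tree, None)
    return parents


def write_case_report(result: dict, out_dir: str | Path) -> None:
    """Write a case result as JSON summary + TSV tables + Newick tree(s).

    ``result`` is the dict form of a :class:`recurrevol.pipeline.CaseResult`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "result.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True, default=_json_default)
    for name in ("relatedness", "clusters", "categories", "exposures", "sharing", "harmonized_mutations"):
        table = result.get("tables", {}).get(name)
        if table is not None:
            pd.DataFrame(table).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    for label, tree in (result.get("trees") or {}).items():
        parents = nested_to_parents(tree)
        lengths = {}

        def collect(node: dict) -> None:
            lengths[node["id"]] = node.get("n_mutations", 0)
            for c in node.get("children", []):
                collect(c)

        collect(tree)
        with open(out / f"tree_{label}.nwk", "w") as fh:
            fh.write(tree_to_newick(parents, lengths) + "\n")


def read_case_report(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "result.json") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
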