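"""Shared fixtures: compact synthetic cases and hand-built patient cases."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recurrevol.simulate import SimulationParams, simulate_case
from recurrevol.types import PatientCase, SampleProfile


SMALL = SimulationParams(mutations_per_tumor=(2_000, 8_000), burden_log_mean=np.log(4_000.0), seed=0)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SMALL


@pytest.fixture(scope="session")
def ancestral_case():
    return simulate_case("ancestral", SMALL, np.random.default_rng(7), "PA")


@pytest.fixture(scope="session")
def denovo_case():
    return simulate_case("de_novo", SMALL, np.random.default_rng(9), "PD")


def make_case(
    rows,
    segments=None,
    purity=(0.5, 0.5),
    ploidy=(2.0, 2.0),
    hepatic=({6}, {6}),
    normal_depth=50,
    genes=None,
):
    """Hand-built two-tumor case.

    ``rows`` is a list of tuples
    ``(chrom, pos, effect, alt_primary, ref_primary, called_p,
       alt_recurrent, ref_recurrent, called_r)``;
    the normal sample gets 0 alt reads at ``normal_depth`` unless a row
    carries an explicit 10th/11th element (alt_normal, ref_normal).
    """
    n = len(rows)
    muts = pd.DataFrame(
        {
            "chrom": [str(r[0]) for r in rows],
            "pos": [int(r[1]) for r in rows],
            "ref": ["A"] * n,
            "alt": ["T"] * n,
            "variant_class": ["SNV"] * n,
            "gene": list(genes) if genes is not None else [""] * n,
            "effect": [r[2] for r in rows],
            "context": ["CAT"] * n,
        }
    )
    alt = np.zeros((n, 3), dtype=np.int64)
    ref = np.zeros((n, 3), dtype=np.int64)
    called = np.zeros((n, 3), dtype=bool)
    for i, r in enumerate(rows):
        alt[i, 0], ref[i, 0], called[i, 0] = r[3], r[4], r[5]
        alt[i, 1], ref[i, 1], called[i, 1] = r[6], r[7], r[8]
        if len(r) > 9:
            alt[i, 2], ref[i, 2] = r[9], r[10]
        else:
            alt[i, 2], ref[i, 2] = 0, normal_depth
    profiles = [
        SampleProfile("T", "P", "primary", purity=purity[0], ploidy=ploidy[0], hepatic_segments=frozenset(hepatic[0])),
        SampleProfile("R", "P", "recurrent", purity=purity[1], ploidy=ploidy[1], hepatic_segments=frozenset(hepatic[1])),
        SampleProfile("N", "P", "normal"),
    ]
    seg_map = {}
    if segments is not None:
        seg = pd.DataFrame(segments, columns=["sample", "chrom", "start", "end", "total_cn"])
        seg["chrom"] = seg["chrom"].astype(str)
        seg_map = {s: g.reset_index(drop=True) for s, g in seg.groupby("sample")}
    return PatientCase(
        patient="P",
        profiles=profiles,
        mutations=muts,
        alt_reads=alt,
        ref_reads=ref,
        called=called,
        segments=seg_map,
    )


@pytest.fixture
def tiny_case_factory():
    return make_case
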