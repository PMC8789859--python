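"""Calibrate the clonality-index cutoff on a user-supplied tumor cohort MAF.

Runs the exact calibration procedure (40/60/80% subsample pairs in
duplicate as positive controls, an equal number of random unrelated tumor
pairs as negatives, accuracy-maximizing threshold, median over 100
repeats) on real cohort data such as a TCGA liver-cancer mutation MAF, and
prints the median cutoff. This needs a sizeable external download and is
therefore not part of the test suite.

Usage:
    python examples/external_cutoff_check.py cohort.maf.tsv

The input must be a TSV with columns ``chrom pos ref alt sample`` (one row
per mutation occurrence; nonsynonymous SNVs/indels only for a faithful
comparison).
"""

import sys

import numpy as np
import pandas as pd

from recurrevol import calibrate_ci_cutoff


def main(path: str) -> None:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = pd.factorize(
        df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    )[0]
    sets = [np.unique(keys[df["sample"] == s]) for s in df["sample"].unique()]
    print(f"{len(sets)} tumors, {sum(len(s) for s in sets)} mutations")
    cal = calibrate_ci_cutoff(sets, repeats=100, seed=0)
    print(f"median optimum cutoff over 100 repeats: {cal.cutoff:.2f}")
    print(f"accuracy at that cutoff (pooled controls): {cal.accuracy:.4f}")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
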