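"""Cluster mutations by CCF and build the subclonal architecture.

One ancestral case is clustered with the truncated binomial-mixture EM,
small/silent-only clusters are filtered, categories assigned, and the
pigeonhole tree constructed. The Newick string carries cluster ids with
mutation counts as branch lengths; compare the per-sample CCF centers
against the printed truth.
"""

import numpy as np

from recurrevol import (
    build_subclonal_architecture,
    classify_cluster_categories,
    cluster_mutations,
    filter_clusters,
    harmonize_case,
)
from recurrevol.simulate import SimulationParams, simulate_case

params = SimulationParams(mutations_per_tumor=(2_000, 8_000), burden_log_mean=float(np.log(4_000.0)))
case, truth = simulate_case("ancestral", params, np.random.default_rng(42), "P1")
print("true cluster CCFs:")
print(truth.cluster_ccfs.round(3))

hc = harmonize_case(case)
clusters = filter_clusters(cluster_mutations(hc, seed=1), len(hc.union_rows()))
roles = {p.sample: p.role for p in case.profiles}
assign = classify_cluster_categories(clusters, roles, "ancestral")

print("\ninferred clusters:")
for c in clusters:
    print(f"  {c.cluster_id}: n={c.size:5d} ccf={c.ccf.round(3).to_dict()} -> {assign.categories[c.cluster_id]}")

tree = build_subclonal_architecture(clusters)
print("\narchitecture (child -> parent):", {k: v for k, v in tree.parents.items() if v})
print("newick:", tree.newick())
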