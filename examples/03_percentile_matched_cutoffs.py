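"""Translate a clustering cutoff between distance measures by percentile.

Different measures live on different scales, so a fixed cutoff is not
comparable across them.  Matching the cutoff's percentile in each measure's
own distance distribution yields gene-set networks with near-identical edge
counts, so any structural differences come from the measures, not the
threshold.
"""

import numpy as np

from pmmclust import (
    DistanceSpec,
    GeneSet,
    GeneSetCollection,
    PPINetwork,
    distance_matrix,
    geneset_network,
    percentile_matched_cutoffs,
)

rng = np.random.default_rng(0)
universe = [f"G{i}" for i in range(60)]
coll = GeneSetCollection(
    [
        GeneSet(f"s{k}", frozenset(rng.choice(universe, int(rng.integers(10, 25)), replace=False)))
        for k in range(12)
    ],
    universe=frozenset(universe),
)
pool = sorted(coll.all_genes())
net = PPINetwork(
    (pool[i], pool[j], float(rng.uniform(0.1, 1.0)))
    for i in range(len(pool))
    for j in range(i + 1, len(pool))
    if rng.uniform() < 0.15
)

dm_mm = distance_matrix(coll, spec=DistanceSpec("MM"))
dm_pmm = distance_matrix(coll, net, DistanceSpec("pMM"))
dm_kappa = distance_matrix(coll, spec=DistanceSpec("KAPPA"))

cutoffs = percentile_matched_cutoffs(dm_mm, [dm_pmm, dm_kappa], ref_cutoff=0.5)
print("percentile-matched cutoffs:", {k: round(v, 4) for k, v in cutoffs.items()})
for dm, key in [(dm_mm, "MM"), (dm_pmm, "pMM"), (dm_kappa, "KAPPA")]:
    g = geneset_network(dm, cutoffs[key])
    print(f"{key:6s} cutoff {cutoffs[key]:.4f} -> {g.number_of_edges()} gene-set edges")
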