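"""Fuzzy-cluster a small gene-set collection and print the cluster table.

Six overlapping gene-sets over a 40-gene universe are clustered under the
Meet/Min distance at cutoff 0.6.  Gene-sets may belong to several clusters;
sets with fewer than two close neighbours stay unclustered ("isolated").
"""

from pmmclust import (
    DistanceSpec,
    GeneSet,
    GeneSetCollection,
    distance_matrix,
    fuzzy_cluster,
)

genes = [f"g{i:02d}" for i in range(40)]
coll = GeneSetCollection(
    [
        GeneSet("alpha", frozenset(genes[0:12])),
        GeneSet("alpha_sub", frozenset(genes[0:6])),
        GeneSet("beta", frozenset(genes[8:20])),
        GeneSet("gamma", frozenset(genes[18:30])),
        GeneSet("delta", frozenset(genes[25:37])),
        GeneSet("lone", frozenset(genes[34:40])),
    ],
    universe=frozenset(genes),
)

dm = distance_matrix(coll, spec=DistanceSpec("MM"))
print("Meet/Min distance matrix:")
print(dm.to_dataframe().round(3).to_string())

result = fuzzy_cluster(dm, cutoff=0.6)
for i, cluster in enumerate(result.clusters):
    print(f"cluster {i}: {sorted(cluster.member_names)}")
print(f"unclustered (isolated): {sorted(result.unclustered)}")
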