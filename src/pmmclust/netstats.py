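"""Cluster-level PPI statistics, percentile-matched cutoffs and hubs.

The average PPI score of a gene group is the mean edge score over *all*
unordered gene pairs of the group, with absent pairs counted as zero — so a
sparse cluster is penalised rather than ignored.

Percentile matching translates a clustering cutoff from one distance measure
to another: the cutoff's rank in the reference distance distribution is
mapped to the same rank in each other distribution (type-1 inverse-ECDF
quantile, so matched cutoffs are realised distances and the resulting
gene-set networks have near-identical edge counts up to ties).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ClusteringResult
from .model import (
    DistanceMatrix,
    GeneSetCollection,
    InvalidInputError,
    PPINetwork,
)

__all__ = [
    "average_ppi",
    "percentile_matched_cutoffs",
    "geneset_network",
    "cluster_ppi_subnetwork",
    "hub_genes",
    "cluster_stats",
    "write_graphml",
    "write_node_link_json",
]


def average_ppi(genes: set[str] | frozenset[str], net: PPINetwork) -> float:
    """Mean PPI score over all unordered pairs of ``genes`` (absent pairs = 0)."""
    genes = sorted(genes)
    n = len(genes)
    if n < 2:
        raise InvalidInputError("need at least 2 genes for an average PPI score")
    total = sum(
        net.score(genes[i], genes[j]) for i in range(n) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) // 2)


def percentile_matched_cutoffs(
    dm_ref: DistanceMatrix,
    dms: list[DistanceMatrix],
    ref_cutoff: float,
) -> dict[str, float]:
    """Map a reference cutoff to equivalent percentile cutoffs of other measures.

    Computes the fraction q of off-diagonal pairs in ``dm_ref`` with distance
    ≤ ``ref_cutoff`` and returns, for each other matrix, its empirical
    q-quantile under the type-1 (inverse-ECDF) convention — the k-th smallest
    value with k = ⌈q·m⌉.  Keys are the measure names; the reference measure
    is included, mapped to ``ref_cutoff`` itself.
    """
    ref_vals = dm_ref.upper_values()
    if ref_vals.size == 0:
        raise InvalidInputError("reference distance matrix has no off-diagonal pairs")
    q = float(np.count_nonzero(ref_vals <= ref_cutoff)) / ref_vals.size

    out: dict[str, float] = {dm_ref.spec.measure.value: float(ref_cutoff)}
    for dm in dms:
        if dm.set_names != dm_ref.set_names:
            raise InvalidInputError("all matrices must cover the same gene-sets")
        vals = np.sort(dm.upper_values())
        if vals.size == 0:
            raise InvalidInputError("distance matrix has no off-diagonal pairs")
        k = int(np.ceil(q * vals.size - 1e-9))
        if k <= 0:
            # no reference pair passes: pick a cutoff below every distance
            out[dm.spec.measure.value] = float(np.nextafter(vals[0], -np.inf))
        else:
            out[dm.spec.measure.value] = float(vals[k - 1])
    return out


def geneset_network(dm: DistanceMatrix, cutoff: float) -> nx.Graph:
    """Gene-set graph: nodes are set names, edges join pairs with d ≤ cutoff."""
    g = nx.Graph()
    g.add_nodes_from(dm.set_names)
    n = len(dm.set_names)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.values[i, j] <= cutoff:
                g.add_edge(dm.set_names[i], dm.set_names[j], distance=float(dm.values[i, j]))
    return g


def cluster_ppi_subnetwork(
    cluster_genes: set[str] | frozenset[str],
    net: PPINetwork,
    score_cutoff: float = 0.0,
    gene_scores: dict[str, float] | None = None,
    gene_score_cutoff: float | None = None,
) -> nx.Graph:
    """PPI subgraph induced on a cluster's genes.

    Keeps genes whose score passes ``gene_score_cutoff`` (strict <, matching
    significance thresholds such as FDR < 0.01; genes without a score are
    dropped when the filter is active) and edges with P ≥ ``score_cutoff``.
    """
    genes = set(cluster_genes)
    if gene_score_cutoff is not None:
        if gene_scores is None:
            raise InvalidInputError("gene_score_cutoff given without gene_scores")
        genes = {g for g in genes if g in gene_scores and gene_scores[g] < gene_score_cutoff}
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for (x, y), s in net.edges.items():
        if x in genes and y in genes and s >= score_cutoff:
            g.add_edge(x, y, score=float(s))
    return g


def hub_genes(graph: nx.Graph) -> list[tuple[str, int]]:
    """All nodes tied at the maximum degree, sorted by name (ties preserved)."""
    if graph.number_of_nodes() == 0:
        return []
    degrees = dict(graph.degree())
    top = max(degrees.values())
    if top == 0:
        return []
    return sorted((n, d) for n, d in degrees.items() if d == top)


def cluster_stats(
    result: ClusteringResult,
    coll: GeneSetCollection,
    net: PPINetwork,
    score_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Per-cluster summary: set count, gene union size, average PPI and hubs.

    ``avg_ppi`` averages over every unordered gene pair of the cluster's gene
    union, absent pairs scoring zero; ``hub_genes`` lists the genes of
    maximal degree in the cluster's PPI subnetwork at ``score_cutoff``.
    """
    rows = []
    for cid, cluster in enumerate(result.clusters):
        genes: set[str] = set()
        for name in cluster.member_names:
            genes |= coll.get(name).genes
        sub = cluster_ppi_subnetwork(genes, net, score_cutoff=score_cutoff)
        hubs = hub_genes(sub)
        rows.append(
            {
                "cluster_id": cid,
                "n_gene_sets": len(cluster),
                "n_genes": len(genes),
                "avg_ppi": average_ppi(genes, net) if len(genes) >= 2 else 0.0,
                "hub_genes": ";".join(f"{g}:{d}" for g, d in hubs),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "n_gene_sets", "n_genes", "avg_ppi", "hub_genes"]
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write a gene-set or PPI graph as GraphML."""
    nx.write_graphml(graph, str(path))


def write_node_link_json(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as node-link JSON (d3 / cytoscape.js friendly)."""
    data = nx.node_link_data(graph, edges="links")
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
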