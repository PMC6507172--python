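"""End-to-end clustering pipeline: read, filter, cluster, export.

Mirrors the interactive workflow as plain file outputs: a cluster table
(CSV), per-cluster PPI statistics (CSV), the gene-set network and
per-cluster PPI subnetworks (GraphML and/or node-link JSON).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .cluster import ClusteringResult, fuzzy_cluster
from .distance import distance_matrix
from .model import (
    DistanceSpec,
    GeneSetCollection,
    InvalidInputError,
    Measure,
    PPINetwork,
)
from .netstats import (
    cluster_ppi_subnetwork,
    cluster_stats,
    geneset_network,
    percentile_matched_cutoffs,
    write_graphml,
    write_node_link_json,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("pmmclust")


@dataclass
class PipelineConfig:
    """Everything the clustering pipeline needs.

    ``cutoff_mode="absolute"`` applies ``cutoff`` directly to the chosen
    measure; ``"mm-percentile"`` interprets ``cutoff`` as a Meet/Min cutoff
    and maps it to the chosen measure by percentile matching.
    """

    measure: str = "pMM"
    alpha: float = 1.0
    cutoff: float = 0.5
    cutoff_mode: str = "absolute"
    min_size: int = 10
    max_size: int = 200
    universe_size: int | None = None
    merge_fraction: float = 0.5
    min_seed_size: int = 2
    ppi_score_cutoff: float = 0.5
    gene_score_cutoff: float | None = None
    export: tuple[str, ...] = ("csv", "graphml", "json")


def run_pipeline(
    coll: GeneSetCollection,
    net: PPINetwork,
    cfg: PipelineConfig,
    out_dir: str | Path,
    gene_scores: dict[str, float] | None = None,
) -> ClusteringResult:
    """Filter by set size, compute distances, cluster and write outputs."""
    measure = Measure.parse(cfg.measure)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_before = len(coll)
    coll = coll.filter_by_size(cfg.min_size, cfg.max_size)
    logger.info(
        "size filter [%d, %d]: %d of %d gene-sets retained",
        cfg.min_size, cfg.max_size, len(coll), n_before,
    )
    if len(coll) < 2:
        raise InvalidInputError("fewer than 2 gene-sets survive the size filter")

    spec = DistanceSpec(measure, alpha=cfg.alpha)
    dm = distance_matrix(coll, net, spec, universe_size=cfg.universe_size)

    cutoff = cfg.cutoff
    if cfg.cutoff_mode == "mm-percentile" and measure is not Measure.MM:
        dm_mm = distance_matrix(coll, None, DistanceSpec(Measure.MM))
        cutoff = percentile_matched_cutoffs(dm_mm, [dm], cfg.cutoff)[measure.value]
        logger.info("percentile-matched cutoff: MM %.4g -> %s %.4g",
                    cfg.cutoff, measure.value, cutoff)
    elif cfg.cutoff_mode not in ("absolute", "mm-percentile"):
        raise InvalidInputError(f"unknown cutoff mode: {cfg.cutoff_mode!r}")

    result = fuzzy_cluster(
        dm, cutoff, merge_fraction=cfg.merge_fraction, min_seed_size=cfg.min_seed_size
    )
    logger.info(
        "measure=%s alpha=%g cutoff=%.4g: %d clusters, %d unclustered of %d gene-sets",
        measure.value, cfg.alpha, cutoff, len(result.clusters),
        len(result.unclustered), len(coll),
    )

    if "csv" in cfg.export:
        pio.write_cluster_table(result, coll, out / "clusters.csv")
        cluster_stats(result, coll, net, score_cutoff=cfg.ppi_score_cutoff).to_csv(
            out / "cluster_stats.csv", index=False
        )

    gs_graph = geneset_network(dm, cutoff)
    for name in gs_graph.nodes:
        s = coll.get(name)
        gs_graph.nodes[name]["size"] = len(s)
        if s.score is not None:
            gs_graph.nodes[name]["score"] = s.score
        gs_graph.nodes[name]["direction"] = s.direction.value
        gs_graph.nodes[name]["clusters"] = ";".join(
            str(i) for i in result.memberships(name)
        )
    if "graphml" in cfg.export:
        write_graphml(gs_graph, out / "geneset_network.graphml")
    if "json" in cfg.export:
        write_node_link_json(gs_graph, out / "geneset_network.json")

    for cid, cluster in enumerate(result.clusters):
        genes: set[str] = set()
        for name in cluster.member_names:
            genes |= coll.get(name).genes
        sub = cluster_ppi_subnetwork(
            genes, net, cfg.ppi_score_cutoff, gene_scores, cfg.gene_score_cutoff
        )
        if "graphml" in cfg.export:
            write_graphml(sub, out / f"cluster_{cid}_ppi.graphml")
        if "json" in cfg.export:
            write_node_link_json(sub, out / f"cluster_{cid}_ppi.json")
    return result
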