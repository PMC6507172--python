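"""Readers and writers for gene-set and network file formats.

Supported formats:

* **GMT** — tab-separated: name, description, then member genes, one
  gene-set per line.
* **GSA result table** — CSV/TSV with columns ``name``, ``genes`` (in-cell
  gene list, comma-delimited by default), optional ``score`` (e.g. FDR
  q-value) and ``direction`` (``up``/``down`` or ``+``/``-`` tokens).
* **PPI edge list** — STRING-dialect whitespace/TAB rows of
  ``gene1 gene2 score``, optional header.  ``score_scale="string1000"``
  divides combined scores (0–1000) by 1000 to land on the unit interval.
  Duplicate pairs keep the maximum score; self-edges are dropped with a
  warning.

Gene identifiers are whitespace-trimmed and matched case-sensitively.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .cluster import ClusteringResult
from .model import (
    Direction,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    PPINetwork,
)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_gsa_table",
    "write_gsa_table",
    "read_ppi_edgelist",
    "write_cluster_table",
]

logger = logging.getLogger("pmmclust")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file into a collection (universe defaults to the gene union)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}: line {lineno}: GMT lines need ≥ 3 tab-separated fields"
                )
            name = fields[0].strip()
            if name in seen:
                raise InvalidInputError(f"{path}: line {lineno}: duplicate gene-set {name!r}")
            seen.add(name)
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise InvalidInputError(f"{path}: line {lineno}: gene-set {name!r} is empty")
            sets.append(GeneSet(name, genes, description=fields[1].strip()))
    if not sets:
        raise InvalidInputError(f"{path}: no gene-sets found")
    return GeneSetCollection(sets, universe=frozenset(universe) if universe else None)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.genes)]) + "\n")


def read_gsa_table(
    path: str | Path,
    gene_delimiter: str = ",",
    universe: set[str] | None = None,
) -> GeneSetCollection:
    """Read a gene-set analysis result table.

    Expects columns ``name`` and ``genes`` plus optional ``score`` and
    ``direction``; the separator (comma or tab) is sniffed from the file.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"name", "genes"}
    if not required <= set(df.columns):
        raise InvalidInputError(
            f"{path}: GSA table needs columns {sorted(required)}, found {list(df.columns)}"
        )
    sets: list[GeneSet] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        genes = frozenset(
            g.strip() for g in str(rec["genes"]).split(gene_delimiter) if g.strip()
        )
        if not genes:
            raise InvalidInputError(f"{path}: gene-set {rec['name']!r} has no genes")
        score = None
        if "score" in rec and pd.notna(rec["score"]):
            try:
                score = float(rec["score"])
            except (TypeError, ValueError):
                raise InvalidInputError(
                    f"{path}: non-numeric score {rec['score']!r} for {rec['name']!r}"
                ) from None
        direction = Direction.NONE
        if "direction" in rec and pd.notna(rec["direction"]):
            direction = Direction.parse(rec["direction"])
        sets.append(
            GeneSet(str(rec["name"]).strip(), genes, score=score, direction=direction)
        )
    return GeneSetCollection(sets, universe=frozenset(universe) if universe else None)


def write_gsa_table(coll: GeneSetCollection, path: str | Path, gene_delimiter: str = ",") -> None:
    rows = [
        {
            "name": s.name,
            "genes": gene_delimiter.join(sorted(s.genes)),
            "score": s.score if s.score is not None else "",
            "direction": s.direction.value,
        }
        for s in coll.sets
    ]
    pd.DataFrame(rows, columns=["name", "genes", "score", "direction"]).to_csv(
        path, index=False
    )


def read_ppi_edgelist(
    path: str | Path,
    score_scale: str = "unit",
    max_score_override: float | None = None,
) -> PPINetwork:
    """Read a weighted edge list (``gene1 gene2 score`` per row).

    ``score_scale="string1000"`` rescales STRING combined scores (0–1000)
    to the unit interval.  Duplicate pairs keep the maximum score and
    self-edges are dropped with a logged warning.
    """
    if score_scale not in ("unit", "string1000"):
        raise InvalidInputError(f"unknown score_scale: {score_scale!r}")
    divisor = 1000.0 if score_scale == "string1000" else 1.0
    triples: list[tuple[str, str, float]] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}: line {lineno}: expected 'gene1 gene2 score'"
                )
            x, y = fields[0].strip(), fields[1].strip()
            try:
                s = float(fields[2])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise InvalidInputError(
                    f"{path}: line {lineno}: non-numeric score {fields[2]!r}"
                ) from None
            if s < 0:
                raise InvalidInputError(f"{path}: line {lineno}: negative score {s}")
            if x == y:
                n_self += 1
                continue
            if s == 0:
                continue  # absent pairs already score zero
            triples.append((x, y, s / divisor))
    if n_self:
        logger.warning("%s: dropped %d self-edge rows", path, n_self)
    return PPINetwork(triples, max_score_override=max_score_override)


def write_cluster_table(
    result: ClusteringResult, coll: GeneSetCollection, path: str | Path
) -> None:
    """Write the clustering as CSV: cluster_id, gene_set, set_size, set_score, direction.

    Unclustered gene-sets appear with an empty cluster_id.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster_id", "gene_set", "set_size", "set_score", "direction"])
        for cid, cluster in enumerate(result.clusters):
            for name in sorted(cluster.member_names):
                s = coll.get(name)
                writer.writerow(
                    [cid, name, len(s), s.score if s.score is not None else "", s.direction.value]
                )
        for name in sorted(result.unclustered):
            s = coll.get(name)
            writer.writerow(
                ["", name, len(s), s.score if s.score is not None else "", s.direction.value]
            )
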