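"""Fuzzy seed-and-merge clustering of gene-sets.

The heuristic follows the seed / multiple-linkage style popularised by the
DAVID functional-annotation clustering tool:

1. **Seeds.**  Every gene-set g spawns a candidate seed: its closed
   neighbourhood under the distance cutoff, ``{g} ∪ {h : d(g,h) ≤ cutoff}``.
   Seeds with fewer than ``min_seed_size`` neighbours (i.e. total size
   < min_seed_size + 1) are dropped — a set needs at least two sufficiently
   close partners to anchor a group.

2. **Merging.**  While any two surviving groups share at least
   ``merge_fraction`` of the smaller group's members, they are merged.  The
   lexicographically first qualifying pair (groups ordered by their sorted
   member tuples) is merged each round, which makes the result deterministic
   and independent of the input ordering.

3. Final groups are the clusters; a gene-set may belong to several clusters
   (fuzzy membership), and gene-sets appearing in no cluster are reported as
   unclustered ("isolated").  A gene-set whose own seed was dropped can still
   be absorbed through another set's seed.

Ties at exactly the cutoff are included (d ≤ cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .model import DistanceMatrix, DistanceSpec, InvalidInputError

__all__ = [
    "Cluster",
    "ClusteringResult",
    "Outcome",
    "fuzzy_cluster",
    "classify_trial",
]


@dataclass
class Cluster:
    """One cluster of gene-set names (at least two members)."""

    member_names: frozenset[str]
    label: str | None = None

    def __post_init__(self) -> None:
        self.member_names = frozenset(self.member_names)
        if len(self.member_names) < 2:
            raise InvalidInputError("a cluster needs at least 2 members")

    def __len__(self) -> int:
        return len(self.member_names)

    def __contains__(self, name: str) -> bool:
        return name in self.member_names


@dataclass
class ClusteringResult:
    """Clusters plus the unclustered remainder of a gene-set collection."""

    clusters: list[Cluster]
    unclustered: frozenset[str]
    cutoff: float
    spec: DistanceSpec

    @property
    def clustered_names(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c.member_names
        return frozenset(out)

    @property
    def all_names(self) -> frozenset[str]:
        return self.clustered_names | self.unclustered

    def memberships(self, name: str) -> list[int]:
        """Indices of the clusters containing ``name`` (fuzzy: possibly many)."""
        return [i for i, c in enumerate(self.clusters) if name in c]


class Outcome(str, Enum):
    """Classification of a clustering against two known subgroups."""

    MERGED = "MERGED"
    SEPARATED = "SEPARATED"
    IMPERFECT = "IMPERFECT"


def fuzzy_cluster(
    dm: DistanceMatrix,
    cutoff: float,
    merge_fraction: float = 0.5,
    min_seed_size: int = 2,
) -> ClusteringResult:
    """Cluster a distance matrix with the seed-and-merge fuzzy heuristic.

    Parameters
    ----------
    dm : DistanceMatrix
        Pairwise gene-set distances.
    cutoff : float
        Two gene-sets are neighbours when their distance is ≤ cutoff.
    merge_fraction : float in (0, 1]
        Two groups merge when their overlap covers at least this fraction of
        the smaller group.
    min_seed_size : int
        Minimum number of neighbours a gene-set needs for its seed to
        survive (seed size ≥ min_seed_size + 1).
    """
    names = dm.set_names
    if len(names) < 2:
        raise InvalidInputError("need at least 2 gene-sets to cluster")
    if not (0.0 < merge_fraction <= 1.0):
        raise InvalidInputError(f"merge_fraction must lie in (0, 1], got {merge_fraction}")

    values = dm.values
    seeds: set[frozenset[str]] = set()
    for i, g in enumerate(names):
        nbrs = {names[j] for j in range(len(names)) if j != i and values[i, j] <= cutoff}
        if len(nbrs) >= min_seed_size:
            seeds.add(frozenset(nbrs | {g}))

    # deterministic canonical order: groups sorted by their member tuples
    groups: list[set[str]] = [set(s) for s in sorted(seeds, key=lambda s: tuple(sorted(s)))]

    merged_any = True
    while merged_any:
        merged_any = False
        groups.sort(key=lambda s: tuple(sorted(s)))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                small = min(len(groups[i]), len(groups[j]))
                if len(groups[i] & groups[j]) >= merge_fraction * small:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged_any = True
                    break
            if merged_any:
                break

    groups.sort(key=lambda s: tuple(sorted(s)))
    clusters = [Cluster(frozenset(g)) for g in groups]
    clustered: set[str] = set()
    for c in clusters:
        clustered |= c.member_names
    return ClusteringResult(
        clusters=clusters,
        unclustered=frozenset(names) - clustered,
        cutoff=cutoff,
        spec=dm.spec,
    )


def classify_trial(
    result: ClusteringResult,
    subgroup1: frozenset[str] | set[str],
    subgroup2: frozenset[str] | set[str],
) -> Outcome:
    """Label a clustering as MERGED / SEPARATED / IMPERFECT for two subgroups.

    * MERGED — some cluster contains every member of both subgroups.
    * SEPARATED — each subgroup lies entirely inside some cluster and no
      cluster mixes members of the two subgroups.
    * IMPERFECT — anything else: some cluster mixes the subgroups while at
      least one subgroup member is missing from it, or a subgroup is split
      or partly unclustered.

    Exactly one label applies to every clustering.
    """
    subgroup1 = frozenset(subgroup1)
    subgroup2 = frozenset(subgroup2)
    if not subgroup1 or not subgroup2:
        raise InvalidInputError("subgroups must be non-empty")
    if subgroup1 & subgroup2:
        raise InvalidInputError("subgroups must be disjoint")
    missing = (subgroup1 | subgroup2) - result.all_names
    if missing:
        raise InvalidInputError(f"names absent from clustering result: {sorted(missing)}")

    both = subgroup1 | subgroup2
    if any(both <= c.member_names for c in result.clusters):
        return Outcome.MERGED

    holds1 = any(subgroup1 <= c.member_names for c in result.clusters)
    holds2 = any(subgroup2 <= c.member_names for c in result.clusters)
    mixes = any(
        (c.member_names & subgroup1) and (c.member_names & subgroup2)
        for c in result.clusters
    )
    if holds1 and holds2 and not mixes:
        return Outcome.SEPARATED
    return Outcome.IMPERFECT
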