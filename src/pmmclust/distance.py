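"""Gene-set distance measures.

Three pairwise distances between gene-sets A and B are provided:

* **Meet/Min (MM)** — ``1 - |A ∩ B| / min(|A|, |B|)``: the overlap distance
  used by enrichment-map style tools.  Zero whenever one set contains the
  other, regardless of the larger set's size.

* **PPI-weighted Meet/Min (pMM)** — MM discounted by protein-protein
  interactions between the sets.  For the direction A→B::

      pMM(A→B) = MM(A,B)
                 - (α / min(|A|,|B|)) * Σ_{x ∈ A−B}
                     (w·Σ_{y ∈ A∩B} P(x,y) + Σ_{y ∈ B−A} P(x,y))
                     / (max(P) · (w·|A∩B| + |B−A|))

  with ``w = min(|A|,|B|) / (|A| + |B|)``.  A gene of A−B fully connected to
  every member of B at the maximum score counts as exactly one additional
  overlap.  Interactions landing in A∩B are down-weighted by ``w``, the
  probability that the shared partner "belongs" to the opposite set.  The
  symmetric distance is ``min(pMM(A→B), pMM(B→A))``, clamped to [0, 1] by
  default (the subtraction can otherwise push it below zero when A−B is much
  larger than the smaller set and edges are dense).

* **Cohen's kappa (KAPPA)** — ``1 - (O - E) / (1 - E)`` over the gene
  universe U, where ``O = (|A∩B| + |(A∪B)^c|) / |U|`` and
  ``E = (|A|·|B| + |A^c|·|B^c|) / |U|²`` are the observed and expected
  membership-agreement rates.  Kappa counts co-absences and is therefore
  sensitive to the set-size difference; it is deliberately not clamped and
  can marginally exceed 1 for below-chance agreement (disjoint sets).
"""

from __future__ import annotations

import numpy as np

from .model import (
    DegenerateInputError,
    DistanceMatrix,
    DistanceSpec,
    DistanceTrace,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    Measure,
    PPINetwork,
)

__all__ = [
    "mm_distance",
    "pmm_directed",
    "pmm_distance",
    "kappa_distance",
    "distance_matrix",
    "distance_trace",
]


def _check_nonempty(a: GeneSet, b: GeneSet) -> None:
    if not a.genes or not b.genes:
        raise InvalidInputError("gene-sets must be non-empty")


def mm_distance(a: GeneSet, b: GeneSet) -> float:
    """Meet/Min overlap distance: 1 - |A∩B| / min(|A|, |B|)."""
    _check_nonempty(a, b)
    return 1.0 - len(a.genes & b.genes) / min(len(a.genes), len(b.genes))


def _mm_weight(size_a: int, size_b: int) -> float:
    # down-weight for interactions into the overlap: the chance that a shared
    # gene belongs to the opposite (larger) set
    return min(size_a, size_b) / (size_a + size_b)


def pmm_directed(a: GeneSet, b: GeneSet, net: PPINetwork, alpha: float = 1.0) -> float:
    """Directed PPI-weighted Meet/Min distance pMM(A→B).

    Sums, over every gene x of A−B, its normalised interaction strength with
    the members of B; interactions into the overlap A∩B are down-weighted by
    ``w = min(|A|,|B|)/(|A|+|B|)``.  With ``alpha == 0`` or an edge-free
    network this reduces exactly to the Meet/Min distance.
    """
    _check_nonempty(a, b)
    if not (0.0 <= alpha <= 1.0):
        raise InvalidInputError(f"alpha must lie in [0, 1], got {alpha}")
    mm = mm_distance(a, b)
    if alpha == 0.0 or len(net) == 0:
        return mm

    inter = a.genes & b.genes
    a_only = a.genes - b.genes
    b_only = b.genes - a.genes
    if not a_only:
        return mm
    denom_pairs = _mm_weight(len(a), len(b)) * len(inter) + len(b_only)
    if denom_pairs == 0:  # unreachable for non-empty B, kept defensive
        return mm
    w = _mm_weight(len(a), len(b))
    max_p = net.max_score
    total = 0.0
    for x in a_only:
        s_inter = sum(net.score(x, y) for y in inter)
        s_bonly = sum(net.score(x, y) for y in b_only)
        total += (w * s_inter + s_bonly) / (max_p * denom_pairs)
    return mm - (alpha / min(len(a), len(b))) * total


def pmm_distance(
    a: GeneSet,
    b: GeneSet,
    net: PPINetwork,
    spec: DistanceSpec | None = None,
) -> float:
    """Symmetric PPI-weighted Meet/Min: min of the two directed values.

    Clamped to [0, 1] when ``spec.clamp`` (the default).  Always ≤ the plain
    Meet/Min distance on the same pair.
    """
    if spec is None:
        spec = DistanceSpec(measure=Measure.PMM)
    d = min(pmm_directed(a, b, net, spec.alpha), pmm_directed(b, a, net, spec.alpha))
    if spec.clamp:
        d = min(1.0, max(0.0, d))
    return d


def _kappa_rates(
    n_a: int, n_b: int, n_inter: int, universe_size: int
) -> tuple[float, float]:
    n_union = n_a + n_b - n_inter
    if universe_size < n_union:
        raise InvalidInputError(
            f"universe size {universe_size} smaller than |A ∪ B| = {n_union}"
        )
    observed = (n_inter + (universe_size - n_union)) / universe_size
    expected = (n_a * n_b + (universe_size - n_a) * (universe_size - n_b)) / universe_size**2
    return observed, expected


def kappa_distance(a: GeneSet, b: GeneSet, universe_size: int) -> float:
    """Cohen's kappa distance 1 - (O - E)/(1 - E) over a universe of genes.

    O and E are the observed and chance-expected agreement rates of the two
    membership indicators.  Not clamped: disjoint sets in a large universe
    give a value marginally above 1.
    """
    _check_nonempty(a, b)
    observed, expected = _kappa_rates(
        len(a.genes), len(b.genes), len(a.genes & b.genes), universe_size
    )
    if expected == 1.0:
        raise DegenerateInputError(
            "kappa undefined: expected agreement is 1 (both sets fill the universe)"
        )
    return 1.0 - (observed - expected) / (1.0 - expected)


def distance_trace(
    a: GeneSet,
    b: GeneSet,
    net: PPINetwork,
    alpha: float = 1.0,
    universe_size: int | None = None,
) -> DistanceTrace:
    """Expose the intermediate quantities of the pairwise distances."""
    _check_nonempty(a, b)
    if universe_size is None:
        universe_size = len(a.genes | b.genes)
    observed, expected = _kappa_rates(
        len(a.genes), len(b.genes), len(a.genes & b.genes), universe_size
    )
    return DistanceTrace(
        w=_mm_weight(len(a), len(b)),
        observed=observed,
        expected=expected,
        directed_ab=pmm_directed(a, b, net, alpha),
        directed_ba=pmm_directed(b, a, net, alpha),
    )


# ---------------------------------------------------------------------------
# matrix computation (vectorised)
# ---------------------------------------------------------------------------


def _index_sets(coll: GeneSetCollection) -> tuple[dict[str, int], list[np.ndarray]]:
    genes = sorted(coll.all_genes())
    gidx = {g: i for i, g in enumerate(genes)}
    idx_arrays = [
        np.fromiter((gidx[g] for g in sorted(s.genes)), dtype=np.intp, count=len(s))
        for s in coll.sets
    ]
    return gidx, idx_arrays


def _dense_scores(net: PPINetwork, gidx: dict[str, int]) -> np.ndarray:
    n = len(gidx)
    p = np.zeros((n, n), dtype=float)
    for (x, y), s in net.edges.items():
        ix, iy = gidx.get(x), gidx.get(y)
        if ix is not None and iy is not None:
            p[ix, iy] = s
            p[iy, ix] = s
    return p


def _pmm_directed_indexed(
    ia: np.ndarray, ib: np.ndarray, p: np.ndarray, max_p: float, alpha: float
) -> float:
    inter = np.intersect1d(ia, ib, assume_unique=True)
    mm = 1.0 - inter.size / min(ia.size, ib.size)
    if alpha == 0.0 or p.size == 0:
        return mm
    a_only = np.setdiff1d(ia, ib, assume_unique=True)
    if a_only.size == 0:
        return mm
    b_only = np.setdiff1d(ib, ia, assume_unique=True)
    w = min(ia.size, ib.size) / (ia.size + ib.size)
    denom = max_p * (w * inter.size + b_only.size)
    if denom == 0:
        return mm
    s_inter = p[np.ix_(a_only, inter)].sum() if inter.size else 0.0
    s_bonly = p[np.ix_(a_only, b_only)].sum() if b_only.size else 0.0
    return mm - (alpha / min(ia.size, ib.size)) * (w * s_inter + s_bonly) / denom


def distance_matrix(
    coll: GeneSetCollection,
    net: PPINetwork | None = None,
    spec: DistanceSpec | None = None,
    universe_size: int | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix of a collection under one measure.

    ``universe_size`` (kappa only) defaults to the size of the collection's
    universe.  The PPI network may be omitted for MM and KAPPA.
    """
    if spec is None:
        spec = DistanceSpec()
    if len(coll) < 2:
        raise InvalidInputError("need at least 2 gene-sets for a distance matrix")
    n = len(coll)
    values = np.zeros((n, n), dtype=float)
    measure = spec.measure

    if measure is Measure.KAPPA:
        if universe_size is None:
            universe_size = len(coll.universe)
        sizes = [len(s) for s in coll.sets]
        for i in range(n):
            for j in range(i + 1, n):
                n_inter = len(coll.sets[i].genes & coll.sets[j].genes)
                try:
                    obs, exp = _kappa_rates(sizes[i], sizes[j], n_inter, universe_size)
                    if exp == 1.0:
                        raise DegenerateInputError("expected agreement is 1")
                    values[i, j] = values[j, i] = 1.0 - (obs - exp) / (1.0 - exp)
                except (InvalidInputError, DegenerateInputError) as err:
                    raise type(err)(
                        f"pair ({coll.sets[i].name}, {coll.sets[j].name}): {err}"
                    ) from err
        return DistanceMatrix(coll.names, values, spec)

    gidx, idx = _index_sets(coll)
    if measure is Measure.PMM and net is not None and len(net) > 0 and spec.alpha > 0:
        p = _dense_scores(net, gidx)
        max_p = net.max_score
    else:
        p = np.zeros((0, 0))
        max_p = 1.0

    for i in range(n):
        for j in range(i + 1, n):
            ia, ib = idx[i], idx[j]
            if measure is Measure.MM:
                d = 1.0 - np.intersect1d(ia, ib, assume_unique=True).size / min(
                    ia.size, ib.size
                )
            else:
                d = min(
                    _pmm_directed_indexed(ia, ib, p, max_p, spec.alpha),
                    _pmm_directed_indexed(ib, ia, p, max_p, spec.alpha),
                )
                if spec.clamp:
                    d = min(1.0, max(0.0, d))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(coll.names, values, spec)
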