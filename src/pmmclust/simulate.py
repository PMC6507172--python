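"""Synthetic gene-set cluster generators and the simulation trial runner.

Three scripted scenarios contrast the behaviour of the distance measures
under fuzzy clustering:

* **Case 1** — ten gene-sets in two functionally distinct five-set subgroups.
  Each subgroup samples its sets from its own 60-gene pool; the two pools
  share 20 genes.  Counterpart set pairs across the subgroups share 45–50 %
  of the smaller set's genes, i.e. they straddle the Meet/Min clustering
  boundary at 0.5.  PPIs are placed only *within* each subgroup's pool, so a
  network-aware distance should keep the subgroups apart.

* **Case 2** — as Case 1 but counterpart pairs share only 40–45 % of genes
  (never crossing the Meet/Min boundary) and PPIs are placed only *across*
  the two subgroups, so a network-aware distance should pull them together.

* **Case 3** — a large 200-gene superset contains five small sets (10–15
  genes) drawn from a common 50-gene pool inside it.  Meet/Min-style
  distances put the superset in the cluster (nested distance 0); the kappa
  distance, penalising the size difference, leaves it out.

The gene universe is fixed at 10,000 genes.  Counterpart overlap is realised
by drawing the overlap *fraction* uniformly on the stated interval and
converting it to the nearest integer gene count, so the realised fraction
distribution tracks the interval rather than the integer-feasibility grid.
Edge scores live on [0.15, 0.99] and are assigned to 40 % of the eligible
gene pairs.  Functional-association scores in curated networks are heavily
right-skewed — most edges sit just above the confidence floor — so scores
default to a truncated exponential calibrated so that the average score over
all eligible pairs is 0.11 (i.e. mean assigned score 0.275 at 40 % density);
set ``ppi_score_mean=None`` for a uniform draw, or pass a ``score_sampler``
hook to substitute an empirical distribution.  All sampling flows through a
single seeded generator, so every trial sequence is reproducible from the
configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cluster import Outcome, classify_trial, fuzzy_cluster
from .distance import distance_matrix, kappa_distance, mm_distance
from .model import (
    DistanceSpec,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    Measure,
    PPINetwork,
)
from .netstats import percentile_matched_cutoffs

__all__ = [
    "SimulationConfig",
    "generate_case12",
    "generate_case3",
    "classify_case3",
    "run_trials",
    "summarize_trials",
    "conditional_counts",
    "kappa_size_sweep",
]

#: overlap fraction of counterpart pairs, relative to the smaller set
CASE1_OVERLAP = (0.45, 0.50)
CASE2_OVERLAP = (0.40, 0.45)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic clustering scenarios.

    Defaults encode the scripted study conditions; ``pair_overlap_range``
    is chosen by the case (45–50 % for Case 1, 40–45 % for Case 2) unless
    set explicitly.
    """

    n_universe: int = 10_000
    pool_size: int = 60
    pool_shared: int = 20
    sets_per_subgroup: int = 5
    set_size_range: tuple[int, int] = (15, 40)
    pair_overlap_range: tuple[float, float] | None = None
    ppi_fraction: float = 0.40
    ppi_score_range: tuple[float, float] = (0.15, 0.99)
    ppi_score_mean: float | None = 0.275
    superset_size: int = 200
    case3_pool_size: int = 50
    small_set_size_range: tuple[int, int] = (10, 15)
    n_small_sets: int = 5
    mm_cutoff: float = 0.50
    alpha: float = 1.0
    merge_fraction: float = 0.5
    min_seed_size: int = 2
    n_trials: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_shared >= self.pool_size:
            raise InvalidInputError("pool_shared must be smaller than pool_size")
        for lo, hi in (
            self.set_size_range,
            self.ppi_score_range,
            self.small_set_size_range,
        ):
            if lo > hi:
                raise InvalidInputError(f"ill-ordered range ({lo}, {hi})")
        if self.set_size_range[1] > self.pool_size:
            raise InvalidInputError("set sizes cannot exceed the pool size")
        if not (0.0 <= self.ppi_fraction <= 1.0):
            raise InvalidInputError("ppi_fraction must lie in [0, 1]")
        if self.ppi_score_mean is not None:
            lo, hi = self.ppi_score_range
            if not (lo < self.ppi_score_mean < (lo + hi) / 2):
                raise InvalidInputError(
                    "ppi_score_mean must lie strictly between the score floor "
                    "and the range midpoint (truncated-exponential model)"
                )

    def overlap_range(self, case: int) -> tuple[float, float]:
        if self.pair_overlap_range is not None:
            return self.pair_overlap_range
        if case == 1:
            return CASE1_OVERLAP
        if case == 2:
            return CASE2_OVERLAP
        raise InvalidInputError(f"no overlap range for case {case}")

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        kwargs = {}
        for k, v in data.items():
            if k not in known:
                raise InvalidInputError(f"unknown simulation config key: {k}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@lru_cache(maxsize=4)
def _universe(n: int) -> tuple[np.ndarray, frozenset[str]]:
    ids = np.array([f"g{i:05d}" for i in range(n)])
    return ids, frozenset(ids.tolist())


def _sample_sizes_and_overlap(
    rng: np.random.Generator,
    size_range: tuple[int, int],
    frac_range: tuple[float, float],
    shared_max: int,
    max_retries: int = 1000,
) -> tuple[int, int, int]:
    """Draw two set sizes and an integer overlap realising a target fraction.

    The overlap fraction (relative to the smaller set) is drawn uniformly on
    ``frac_range`` and realised as the nearest integer gene count, clamped to
    the feasible range (at least 1 gene, at most the shared-pool size).
    Resamples the sizes in the rare case no feasible count exists.
    """
    lo, hi = size_range
    flo, fhi = frac_range
    for _ in range(max_retries):
        sa = int(rng.integers(lo, hi + 1))
        sb = int(rng.integers(lo, hi + 1))
        m = min(sa, sb)
        o = int(math.floor(rng.uniform(flo, fhi) * m + 0.5))
        o = min(o, shared_max, sa, sb)
        if o >= 1:
            return sa, sb, o
    raise InvalidInputError(
        f"no feasible overlap for sizes in {size_range} and fraction {frac_range}"
    )


def _unordered_pairs(ids: Sequence[str]) -> list[tuple[str, str]]:
    ids = sorted(ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


@lru_cache(maxsize=8)
def _trunc_exp_rate(lo: float, hi: float, mean: float) -> float:
    """Rate parameter of an exponential truncated to [lo, hi] with given mean."""
    span = hi - lo

    def mean_at(tau: float) -> float:
        z = span / tau
        return lo + tau * (1.0 - z * math.exp(-z) / (1.0 - math.exp(-z)))

    t_lo, t_hi = 1e-4, 1e4
    for _ in range(200):
        t_mid = math.sqrt(t_lo * t_hi)
        if mean_at(t_mid) < mean:
            t_lo = t_mid
        else:
            t_hi = t_mid
    return math.sqrt(t_lo * t_hi)


def _draw_scores(cfg: SimulationConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    lo, hi = cfg.ppi_score_range
    if cfg.ppi_score_mean is None:
        return rng.uniform(lo, hi, size=k)
    tau = _trunc_exp_rate(lo, hi, cfg.ppi_score_mean)
    z = (hi - lo) / tau
    u = rng.uniform(size=k)
    return lo - tau * np.log(1.0 - u * (1.0 - math.exp(-z)))


def _assign_edges(
    pairs: list[tuple[str, str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    score_sampler: Callable[[np.random.Generator, int], np.ndarray] | None,
) -> PPINetwork:
    k = int(round(cfg.ppi_fraction * len(pairs)))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    if score_sampler is not None:
        scores = np.asarray(score_sampler(rng, k), dtype=float)
    else:
        scores = _draw_scores(cfg, rng, k)
    return PPINetwork(
        (pairs[i][0], pairs[i][1], float(s)) for i, s in zip(chosen, scores)
    )


def generate_case12(
    cfg: SimulationConfig,
    case: int,
    rng: np.random.Generator,
    score_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> tuple[GeneSetCollection, PPINetwork, frozenset[str], frozenset[str]]:
    """One Case-1 or Case-2 instance: collection, network and the two subgroups.

    Counterpart pairs (set i of each subgroup) draw their overlap genes from
    the 20 shared pool genes first and fill the remainder from their pool's
    exclusive genes, so the realised overlap fraction is exact.  "Within"
    PPI pairs (Case 1) are all unordered pairs inside either 60-gene pool;
    "across" pairs (Case 2) join the two pools' exclusive parts.
    """
    if case not in (1, 2):
        raise InvalidInputError(f"case must be 1 or 2, got {case}")
    ids, universe = _universe(cfg.n_universe)
    n_excl = cfg.pool_size - cfg.pool_shared
    picked = rng.choice(ids, size=cfg.pool_shared + 2 * n_excl, replace=False)
    shared = picked[: cfg.pool_shared]
    excl1 = picked[cfg.pool_shared : cfg.pool_shared + n_excl]
    excl2 = picked[cfg.pool_shared + n_excl :]

    frac_range = cfg.overlap_range(case)
    sets: list[GeneSet] = []
    sub1: list[str] = []
    sub2: list[str] = []
    for i in range(cfg.sets_per_subgroup):
        sa, sb, o = _sample_sizes_and_overlap(
            rng, cfg.set_size_range, frac_range, cfg.pool_shared
        )
        common = rng.choice(shared, size=o, replace=False)
        genes_a = frozenset(common) | frozenset(rng.choice(excl1, size=sa - o, replace=False))
        genes_b = frozenset(common) | frozenset(rng.choice(excl2, size=sb - o, replace=False))
        name_a, name_b = f"S1_{i + 1}", f"S2_{i + 1}"
        sets.append(GeneSet(name_a, genes_a))
        sets.append(GeneSet(name_b, genes_b))
        sub1.append(name_a)
        sub2.append(name_b)

    pool1 = np.concatenate([shared, excl1])
    pool2 = np.concatenate([shared, excl2])
    if case == 1:
        pairs = sorted(set(_unordered_pairs(pool1)) | set(_unordered_pairs(pool2)))
    else:
        pairs = sorted(
            (min(x, y), max(x, y)) for x in excl1.tolist() for y in excl2.tolist()
        )
    net = _assign_edges(pairs, cfg, rng, score_sampler)
    coll = GeneSetCollection(sets, universe=universe)
    return coll, net, frozenset(sub1), frozenset(sub2)


def generate_case3(
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, str, frozenset[str]]:
    """One Case-3 instance: a 200-gene superset nesting five small sets.

    The small sets (10–15 genes) are sampled from a 50-gene pool inside the
    superset, which guarantees nesting and makes pairwise overlaps among the
    small sets likely.
    """
    ids, universe = _universe(cfg.n_universe)
    super_genes = rng.choice(ids, size=cfg.superset_size, replace=False)
    pool = super_genes[: cfg.case3_pool_size]
    sets = [GeneSet("SUPER", frozenset(super_genes))]
    small: list[str] = []
    lo, hi = cfg.small_set_size_range
    for i in range(cfg.n_small_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SMALL_{i + 1}"
        sets.append(GeneSet(name, frozenset(rng.choice(pool, size=size, replace=False))))
        small.append(name)
    return GeneSetCollection(sets, universe=universe), "SUPER", frozenset(small)


def classify_case3(result, superset_name: str, small_names: frozenset[str]) -> Outcome:
    """Case-3 outcome: did the superset join the small sets' cluster?

    MERGED — some cluster holds the superset together with all small sets;
    SEPARATED — all small sets share a cluster and the superset belongs to no
    cluster at all (it was excluded as isolated); IMPERFECT — anything else.
    """
    full = small_names | {superset_name}
    if any(full <= c.member_names for c in result.clusters):
        return Outcome.MERGED
    smalls_held = any(small_names <= c.member_names for c in result.clusters)
    super_clustered = any(superset_name in c.member_names for c in result.clusters)
    if smalls_held and not super_clustered:
        return Outcome.SEPARATED
    return Outcome.IMPERFECT


def _trial_labels(
    coll: GeneSetCollection,
    net: PPINetwork,
    cfg: SimulationConfig,
    measures: Sequence[Measure],
) -> dict[Measure, object]:
    """Cluster one instance under every measure at percentile-matched cutoffs."""
    spec_mm = DistanceSpec(Measure.MM)
    dm_mm = distance_matrix(coll, None, spec_mm)
    dms = {Measure.MM: dm_mm}
    for m in measures:
        if m is Measure.PMM:
            dms[m] = distance_matrix(
                coll, net, DistanceSpec(Measure.PMM, alpha=cfg.alpha)
            )
        elif m is Measure.KAPPA:
            dms[m] = distance_matrix(
                coll, None, DistanceSpec(Measure.KAPPA), universe_size=cfg.n_universe
            )
    others = [dms[m] for m in measures if m is not Measure.MM]
    cutoffs = percentile_matched_cutoffs(dm_mm, others, cfg.mm_cutoff)
    results = {}
    for m in measures:
        results[m] = fuzzy_cluster(
            dms[m],
            cutoffs[m.value],
            merge_fraction=cfg.merge_fraction,
            min_seed_size=cfg.min_seed_size,
        )
    return results


def run_trials(
    case: int,
    cfg: SimulationConfig,
    measures: Sequence[str | Measure] = ("MM", "pMM", "KAPPA"),
    seed: int | None = None,
    score_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run ``cfg.n_trials`` simulated clustering trials of one case.

    Each trial builds a fresh collection (and network for Cases 1–2),
    computes the Meet/Min matrix, translates the MM cutoff to the other
    measures by percentile matching *within that trial's distances*, fuzzy
    clusters under every measure and classifies the outcome.  Returns a
    tidy frame with one row per trial and one outcome column per measure.
    """
    measures = [Measure.parse(m) for m in measures]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[dict] = []
    for t in range(cfg.n_trials):
        if case in (1, 2):
            coll, net, sub1, sub2 = generate_case12(cfg, case, rng, score_sampler)
            results = _trial_labels(coll, net, cfg, measures)
            row = {"trial": t}
            for m in measures:
                row[m.value] = classify_trial(results[m], sub1, sub2).value
        elif case == 3:
            coll, super_name, small_names = generate_case3(cfg, rng)
            results = _trial_labels(coll, PPINetwork(), cfg, measures)
            row = {"trial": t}
            for m in measures:
                row[m.value] = classify_case3(results[m], super_name, small_names).value
        else:
            raise InvalidInputError(f"unknown simulation case: {case}")
        records.append(row)
    return pd.DataFrame.from_records(records)


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Outcome frequency table: rows MERGED/SEPARATED/IMPERFECT, one column per measure."""
    labels = [o.value for o in Outcome]
    cols = [c for c in trials.columns if c != "trial"]
    out = pd.DataFrame(0, index=labels, columns=cols, dtype=int)
    for c in cols:
        counts = trials[c].value_counts()
        for label in labels:
            out.loc[label, c] = int(counts.get(label, 0))
    out.index.name = "outcome"
    return out


def conditional_counts(
    trials: pd.DataFrame,
    given_measure: str | Measure,
    given_label: str | Outcome,
    measure: str | Measure,
) -> pd.Series:
    """Outcome counts of ``measure`` among trials where ``given_measure`` had ``given_label``."""
    gm = Measure.parse(given_measure).value
    m = Measure.parse(measure).value
    gl = Outcome(given_label).value if not isinstance(given_label, Outcome) else given_label.value
    sub = trials[trials[gm] == gl]
    labels = [o.value for o in Outcome]
    counts = sub[m].value_counts()
    return pd.Series({label: int(counts.get(label, 0)) for label in labels}, name=m)


def kappa_size_sweep(
    n_a: int = 10,
    b_sizes: Sequence[int] | None = None,
    universe_size: int = 10_000,
) -> pd.DataFrame:
    """Kappa distance of a nested pair A ⊂ B as the superset size grows.

    A has ``n_a`` genes, fully contained in B whose size sweeps ``b_sizes``
    (default 10..200).  Returns columns ``size_b``, ``mm`` (identically 0 for
    nested sets) and ``kappa`` (increasing with the size gap).
    """
    if b_sizes is None:
        b_sizes = range(n_a, 201)
    ids, _ = _universe(universe_size)
    a = GeneSet("A", frozenset(ids[:n_a].tolist()))
    rows = []
    for nb in b_sizes:
        if nb < n_a:
            raise InvalidInputError("B must contain A: size of B below size of A")
        b = GeneSet("B", frozenset(ids[:nb].tolist()))
        rows.append(
            {
                "size_b": int(nb),
                "mm": mm_distance(a, b),
                "kappa": kappa_distance(a, b, universe_size),
            }
        )
    return pd.DataFrame(rows)
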