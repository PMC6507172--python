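"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every distance from first principles — explicit loops
over gene pairs and an explicitly materialised membership contingency table —
and deliberately share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmmclust import GeneSet, GeneSetCollection, PPINetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mm_bruteforce(a: GeneSet, b: GeneSet) -> float:
    shared = sum(1 for g in a.genes if g in b.genes)
    return 1.0 - shared / min(len(a.genes), len(b.genes))


def pmm_directed_bruteforce(
    a: GeneSet, b: GeneSet, net: PPINetwork, alpha: float = 1.0
) -> float:
    """Triple-loop evaluation of the directed PPI-weighted Meet/Min distance."""
    mm = mm_bruteforce(a, b)
    if alpha == 0 or len(net) == 0:
        return mm
    size_a, size_b = len(a.genes), len(b.genes)
    w = (size_a if size_a <= size_b else size_b) / (size_a + size_b)
    inter = [g for g in a.genes if g in b.genes]
    a_only = [g for g in a.genes if g not in b.genes]
    b_only = [g for g in b.genes if g not in a.genes]
    if not a_only:
        return mm
    denom = net.max_score * (w * len(inter) + len(b_only))
    if denom == 0:
        return mm
    total = 0.0
    for x in a_only:
        num = 0.0
        for y in inter:
            num += w * net.score(x, y)
        for y in b_only:
            num += net.score(x, y)
        total += num / denom
    return mm - alpha / min(size_a, size_b) * total


def kappa_bruteforce(a: GeneSet, b: GeneSet, universe: list[str]) -> float:
    """Cohen's kappa distance from an explicit 2x2 membership contingency table."""
    n11 = n10 = n01 = n00 = 0
    for g in universe:
        in_a, in_b = g in a.genes, g in b.genes
        if in_a and in_b:
            n11 += 1
        elif in_a:
            n10 += 1
        elif in_b:
            n01 += 1
        else:
            n00 += 1
    n = len(universe)
    observed = (n11 + n00) / n
    expected = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / n**2
    return 1.0 - (observed - expected) / (1.0 - expected)


def random_instance(
    rng: np.random.Generator,
    max_size: int = 30,
    n_universe: int = 100,
    edge_prob: float = 0.3,
) -> tuple[GeneSet, GeneSet, PPINetwork]:
    """A random pair of overlapping gene-sets plus a random weighted network."""
    universe = [f"g{i}" for i in range(n_universe)]
    size_a = int(rng.integers(1, max_size + 1))
    size_b = int(rng.integers(1, max_size + 1))
    a = GeneSet("A", frozenset(rng.choice(universe, size_a, replace=False)))
    b = GeneSet("B", frozenset(rng.choice(universe, size_b, replace=False)))
    pool = sorted(a.genes | b.genes)
    triples = []
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            if rng.uniform() < edge_prob:
                triples.append((pool[i], pool[j], float(rng.uniform(0.05, 1.0))))
    return a, b, PPINetwork(triples)


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    """Six small gene-sets, one nesting another, over a 40-gene universe."""
    genes = [f"g{i:02d}" for i in range(40)]
    sets = [
        GeneSet("alpha", frozenset(genes[0:12])),
        GeneSet("alpha_sub", frozenset(genes[0:6])),
        GeneSet("beta", frozenset(genes[8:20])),
        GeneSet("gamma", frozenset(genes[18:30])),
        GeneSet("delta", frozenset(genes[25:37])),
        GeneSet("lone", frozenset(genes[34:40])),
    ]
    return GeneSetCollection(sets, universe=frozenset(genes))


@pytest.fixture
def toy_network(toy_collection) -> PPINetwork:
    rng = np.random.default_rng(0)
    genes = sorted(toy_collection.all_genes())
    triples = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.uniform() < 0.2:
                triples.append((genes[i], genes[j], float(rng.uniform(0.1, 1.0))))
    return PPINetwork(triples)
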