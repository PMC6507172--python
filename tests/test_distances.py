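"""Distance-measure unit and property tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pmmclust import (
    DegenerateInputError,
    DistanceSpec,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    PPINetwork,
    distance_matrix,
    distance_trace,
    kappa_distance,
    mm_distance,
    pmm_directed,
    pmm_distance,
)
from conftest import kappa_bruteforce, pmm_directed_bruteforce, random_instance


def make_set(name, ids):
    return GeneSet(name, frozenset(ids))


GENES = [f"g{i}" for i in range(300)]


class TestMeetMin:
    def test_identity_is_zero(self):
        a = make_set("a", GENES[:7])
        assert mm_distance(a, a) == 0.0

    def test_nested_is_zero_regardless_of_superset_size(self):
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[:200])
        assert mm_distance(a, b) == 0.0
        assert mm_distance(b, a) == 0.0

    def test_partial_overlap(self):
        # |A|=10, |B|=20, |A∩B|=6 -> 1 - 6/10
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[4:24])
        assert mm_distance(a, b) == pytest.approx(0.4)

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidInputError):
            GeneSet("x", frozenset())


class TestPMM:
    def _worked_example(self):
        # |A|=10, |B|=20 sharing 6 genes; one gene of A-B wired to all of B at score 1
        a = make_set("a", GENES[:4] + GENES[100:106])
        b = make_set("b", GENES[100:106] + GENES[200:214])
        hub = GENES[0]
        net = PPINetwork([(hub, y, 1.0) for y in sorted(b.genes)])
        return a, b, net

    def test_directed_fully_connected_gene_counts_as_one_overlap(self):
        a, b, net = self._worked_example()
        # one more overlap: 1 - 7/10
        assert pmm_directed(a, b, net) == pytest.approx(0.3)

    def test_symmetric_min_of_directions(self):
        a, b, net = self._worked_example()
        # reverse direction: each of the 14 genes of B-A links to the hub
        assert pmm_directed(b, a, net) == pytest.approx(1 - 0.6 - (1 / 10) * (14 / 6))
        assert pmm_distance(a, b, net) == pytest.approx(0.1667, abs=5e-5)

    def test_no_edges_reduces_to_mm(self):
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[4:24])
        assert pmm_distance(a, b, PPINetwork()) == mm_distance(a, b)

    def test_alpha_zero_reduces_to_mm(self):
        a, b, net = self._worked_example()
        spec = DistanceSpec("pMM", alpha=0.0)
        assert pmm_distance(a, b, net, spec) == mm_distance(a, b)

    def test_identical_sets_zero(self):
        a, _, net = self._worked_example()
        assert pmm_distance(a, a, net) == 0.0

    def test_alpha_out_of_range(self):
        a, b, net = self._worked_example()
        with pytest.raises(InvalidInputError):
            pmm_directed(a, b, net, alpha=1.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_directed_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a, b, net = random_instance(rng)
            alpha = float(rng.uniform(0, 1))
            assert pmm_directed(a, b, net, alpha) == pytest.approx(
                pmm_directed_bruteforce(a, b, net, alpha), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_never_exceeds_mm(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, net = random_instance(rng)
            assert pmm_distance(a, b, net) <= mm_distance(a, b) + 1e-12

    def test_scaling_edge_scores_is_a_noop(self):
        rng = np.random.default_rng(3)
        a, b, net = random_instance(rng)
        for c in (0.1, 2.5, 1000.0):
            assert pmm_distance(a, b, net.scaled(c)) == pytest.approx(
                pmm_distance(a, b, net), abs=1e-12
            )

    def test_raising_a_cross_edge_never_increases_distance(self):
        rng = np.random.default_rng(11)
        a, b, net = random_instance(rng, edge_prob=0.5)
        base = pmm_distance(a, b, net)
        a_only = sorted(a.genes - b.genes)
        b_all = sorted(b.genes)
        if not a_only:
            pytest.skip("degenerate draw: A contained in B")
        x, y = a_only[0], b_all[0]
        edges = net.edges
        # raise towards (but not past) the current maximum, keeping max(P) fixed
        edges[(min(x, y), max(x, y))] = net.max_score
        assert pmm_distance(a, b, PPINetwork(edges)) <= base + 1e-12

    def test_negative_values_clamped_by_default(self):
        # one shared gene, dense strong edges: raw pMM drops below zero
        a = make_set("a", GENES[:1] + GENES[10:30])
        b = make_set("b", GENES[:2])
        triples = [
            (x, y, 1.0) for x in GENES[10:30] for y in GENES[:2]
        ]
        net = PPINetwork(triples)
        raw = min(pmm_directed(a, b, net), pmm_directed(b, a, net))
        assert raw < 0
        assert pmm_distance(a, b, net) == 0.0
        unclamped = pmm_distance(a, b, net, DistanceSpec("pMM", clamp=False))
        assert unclamped == pytest.approx(raw)


class TestKappa:
    def test_identical_sets_zero(self):
        a = make_set("a", GENES[:10])
        assert kappa_distance(a, a, 10_000) == pytest.approx(0.0, abs=1e-12)

    def test_nested_pair_matches_contingency_oracle(self):
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[:200])
        got = kappa_distance(a, b, 10_000)
        assert got == pytest.approx(0.9065, abs=5e-5)

    def test_disjoint_sets_slightly_exceed_one(self):
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[10:20])
        got = kappa_distance(a, b, 10_000)
        assert got == pytest.approx(1.001, abs=5e-4)
        assert got > 1.0

    def test_universe_smaller_than_union_rejected(self):
        a = make_set("a", GENES[:10])
        b = make_set("b", GENES[5:20])
        with pytest.raises(InvalidInputError):
            kappa_distance(a, b, 15)

    def test_degenerate_full_universe(self):
        a = make_set("a", GENES[:10])
        with pytest.raises(DegenerateInputError):
            kappa_distance(a, a, 10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_contingency_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n_universe = int(rng.integers(50, 1000))
            universe = [f"g{i}" for i in range(n_universe)]
            a = make_set("a", rng.choice(universe, int(rng.integers(1, 40)), replace=False))
            b = make_set("b", rng.choice(universe, int(rng.integers(1, 40)), replace=False))
            assert kappa_distance(a, b, n_universe) == pytest.approx(
                kappa_bruteforce(a, b, universe), abs=1e-12
            )

    def test_agrees_with_sklearn_cohen_kappa(self):
        """Cross-check against an established kappa implementation."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(400)]
        for _ in range(10):
            a = make_set("a", rng.choice(universe, 25, replace=False))
            b = make_set("b", rng.choice(universe, 40, replace=False))
            ind_a = [g in a.genes for g in universe]
            ind_b = [g in b.genes for g in universe]
            expected = 1.0 - cohen_kappa_score(ind_a, ind_b)
            assert kappa_distance(a, b, len(universe)) == pytest.approx(expected, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_sets_give_zero_offdiagonal(self):
        coll = GeneSetCollection(
            [make_set("a", GENES[:5]), make_set("b", GENES[:5])],
            universe=frozenset(GENES),
        )
        for measure in ("MM", "pMM", "KAPPA"):
            dm = distance_matrix(coll, PPINetwork(), DistanceSpec(measure))
            assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
            assert np.allclose(np.diag(dm.values), 0.0)

    def test_disjoint_sets_mm_is_one(self):
        coll = GeneSetCollection(
            [make_set("a", GENES[:5]), make_set("b", GENES[5:10]), make_set("c", GENES[10:15])]
        )
        dm = distance_matrix(coll, spec=DistanceSpec("MM"))
        off = dm.upper_values()
        assert np.allclose(off, 1.0)

    def test_pmm_matrix_elementwise_below_mm(self, toy_collection, toy_network):
        mm = distance_matrix(toy_collection, spec=DistanceSpec("MM"))
        pmm = distance_matrix(toy_collection, toy_network, DistanceSpec("pMM"))
        assert np.all(pmm.values <= mm.values + 1e-12)
        assert np.allclose(pmm.values, pmm.values.T)

    def test_matrix_agrees_with_pairwise_ops(self, toy_collection, toy_network):
        spec = DistanceSpec("pMM", alpha=0.7)
        dm = distance_matrix(toy_collection, toy_network, spec)
        for i, a in enumerate(toy_collection.sets):
            for j, b in enumerate(toy_collection.sets):
                if i < j:
                    assert dm.values[i, j] == pytest.approx(
                        pmm_distance(a, b, toy_network, spec), abs=1e-12
                    )
        dmk = distance_matrix(toy_collection, spec=DistanceSpec("KAPPA"))
        u = len(toy_collection.universe)
        for i, a in enumerate(toy_collection.sets):
            for j, b in enumerate(toy_collection.sets):
                if i < j:
                    assert dmk.values[i, j] == pytest.approx(
                        kappa_distance(a, b, u), abs=1e-12
                    )

    def test_single_set_rejected(self):
        coll = GeneSetCollection([make_set("a", GENES[:5])])
        with pytest.raises(InvalidInputError):
            distance_matrix(coll, spec=DistanceSpec("MM"))

    def test_error_names_offending_pair(self):
        coll = GeneSetCollection(
            [make_set("a", GENES[:5]), make_set("b", GENES[:5])],
        )
        with pytest.raises(InvalidInputError, match="a.*b|b.*a"):
            distance_matrix(coll, spec=DistanceSpec("KAPPA"), universe_size=3)


class TestTraceAndTypes:
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 20))
    def test_trace_invariants(self, na, nb, shared):
        shared = min(shared, na, nb)
        a = make_set("a", GENES[:na])
        b = make_set("b", GENES[na - shared : na - shared + nb])
        tr = distance_trace(a, b, PPINetwork(), universe_size=500)
        assert 0 < tr.w <= 0.5
        assert 0.0 <= tr.observed <= 1.0
        assert 0.0 <= tr.expected <= 1.0
        assert tr.directed_ab == mm_distance(a, b)

    def test_duplicate_set_names_rejected(self):
        with pytest.raises(InvalidInputError):
            GeneSetCollection([make_set("a", GENES[:3]), make_set("a", GENES[3:6])])

    def test_network_rejects_self_edges_and_bad_scores(self):
        with pytest.raises(InvalidInputError):
            PPINetwork([("x", "x", 0.5)])
        with pytest.raises(InvalidInputError):
            PPINetwork([("x", "y", -0.2)])

    def test_duplicate_edges_keep_max(self):
        net = PPINetwork([("a", "b", 0.4), ("b", "a", 0.7)])
        assert net.score("a", "b") == 0.7
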