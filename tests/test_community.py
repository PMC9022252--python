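"""Modularity, Louvain, NMI, Jaccard and the degree-preserving null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from stagenet.community import (
    Partition,
    degree_preserving_randomize,
    jaccard_matrix,
    louvain,
    modularity,
    nmi,
    nmi_permutation_test,
)

from conftest import exhaustive_best_partition, make_network, random_gnm_network


def clique_edges(nodes):
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


class TestModularity:
    def test_single_community_is_zero(self):
        net = make_network([("a", "b"), ("b", "c"), ("a", "c")])
        part = {n: 0 for n in "abc"}
        assert modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_give_half(self):
        net = make_network(clique_edges(list("abc")) + clique_edges(list("xyz")))
        part = {**{n: 0 for n in "abc"}, **{n: 1 for n in "xyz"}}
        assert modularity(net, part) == pytest.approx(0.5)

    def test_singleton_partition_of_one_edge_is_minus_half(self):
        net = make_network([("a", "b")])
        assert modularity(net, {"a": 0, "b": 1}) == pytest.approx(-0.5)

    def test_empty_edge_set_is_an_error(self):
        net = make_network([])
        with pytest.raises(ValueError, match="empty edge set"):
            modularity(net, {})

    def test_weighted_variant_uses_edge_weights(self):
        net = make_network([("a", "b", 2.0), ("c", "d", 1.0), ("b", "c", 1.0)])
        part = {"a": 0, "b": 0, "c": 1, "d": 1}
        w, wc0, wc1 = 4.0, 2.0, 1.0
        s0, s1 = 2.0 + 3.0, 2.0 + 1.0  # strengths of {a,b}, {c,d}
        expected = (wc0 / w - (s0 / (2 * w)) ** 2) + (wc1 / w - (s1 / (2 * w)) ** 2)
        assert modularity(net, part) == pytest.approx(expected, rel=1e-12)


class TestLouvain:
    def test_two_cliques_with_bridge_match_exhaustive_optimum(self):
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        net = make_network(
            clique_edges(left) + clique_edges(right) + [(left[0], right[0])]
        )
        part = louvain(net, seed=0)
        comms = {frozenset(c) for c in part.communities().values()}
        assert comms == {frozenset(left), frozenset(right)}
        _, best_q = exhaustive_best_partition(net)
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_complete_graph_single_community(self):
        net = make_network(clique_edges([f"n{i}" for i in range(6)]))
        part = louvain(net, seed=0)
        assert part.n_communities() == 1
        _, best_q = exhaustive_best_partition(net)
        assert part.q == pytest.approx(best_q, abs=1e-12)  # Q = 0 is optimal

    def test_no_community_spans_disconnected_components(self):
        comp_a = clique_edges(list("abcd"))
        comp_b = clique_edges(list("wxyz"))
        part = louvain(make_network(comp_a + comp_b), seed=3)
        for comm in part.communities().values():
            assert comm <= set("abcd") or comm <= set("wxyz")

    def test_q_at_least_singleton_partition(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            net = random_gnm_network(15, 30, rng)
            part = louvain(net, seed=trial)
            nodes = sorted(net.edge_bearing_nodes())
            singleton_q = modularity(net, {n: i for i, n in enumerate(nodes)})
            assert part.q >= singleton_q - 1e-12

    def test_returned_q_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        net = random_gnm_network(20, 45, rng)
        part = louvain(net, seed=1)
        assert part.q == pytest.approx(modularity(net, part), abs=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        net = random_gnm_network(30, 70, rng)
        assert louvain(net, seed=9).assignment == louvain(net, seed=9).assignment

    def test_agrees_with_networkx_reference_on_clique_fixture(self):
        """Independent Louvain implementation finds the same optimum."""
        import networkx as nx

        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        net = make_network(
            clique_edges(left) + clique_edges(right) + [(left[0], right[0])]
        )
        ours = louvain(net, seed=0)
        ref = nx.community.louvain_communities(net.to_networkx(), seed=0)
        assert {frozenset(c) for c in ref} == {
            frozenset(c) for c in ours.communities().values()
        }

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            louvain(make_network([]), seed=0)


class TestNMI:
    def test_self_comparison_is_one(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 2}, 0.0)
        assert nmi(p, p) == 1.0

    def test_independent_partitions_are_zero(self):
        a = Partition({"a": 0, "b": 0, "c": 1, "d": 1}, 0.0)
        b = Partition({"a": 0, "b": 1, "c": 0, "d": 1}, 0.0)
        assert nmi(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_entropy_convention(self):
        a = Partition({"a": 0, "b": 0, "c": 1, "d": 1}, 0.0)
        b = Partition({n: 0 for n in "abcd"}, 0.0)
        assert nmi(a, b) == 0.0
        assert nmi(b, b) == 1.0  # identical single-community partitions

    def test_mismatched_node_sets_error(self):
        a = Partition({"a": 0}, 0.0)
        b = Partition({"b": 0}, 0.0)
        with pytest.raises(ValueError, match="same node set"):
            nmi(a, b)

    def test_agrees_with_sklearn_on_random_partitions(self):
        """Sum-of-entropies NMI == sklearn arithmetic-mean NMI, 1e-12."""
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(40)]
        for _ in range(100):
            la = rng.integers(0, 5, size=40)
            lb = rng.integers(0, 4, size=40)
            a = Partition(dict(zip(nodes, map(int, la))), 0.0)
            b = Partition(dict(zip(nodes, map(int, lb))), 0.0)
            expected = normalized_mutual_info_score(la, lb)
            if len(set(la)) == 1 and len(set(lb)) == 1:
                continue
            assert nmi(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 4), min_size=4, max_size=30),
        st.lists(st.integers(0, 4), min_size=4, max_size=30),
        st.permutations(list(range(5))),
    )
    def test_symmetric_and_relabel_invariant(self, la, lb, perm):
        n = min(len(la), len(lb))
        nodes = [f"n{i}" for i in range(n)]
        a = Partition(dict(zip(nodes, la[:n])), 0.0)
        b = Partition(dict(zip(nodes, lb[:n])), 0.0)
        b_relab = Partition({k: perm[v] for k, v in b.assignment.items()}, 0.0)
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)
        assert nmi(a, b) == pytest.approx(nmi(a, b_relab), abs=1e-12)


class TestJaccard:
    def test_examples(self):
        a = Partition({"a": 0, "b": 0, "c": 0, "x": 1}, 0.0)
        b = Partition({"b": 0, "c": 0, "d": 0, "x": 1}, 0.0)
        j = jaccard_matrix(a, b)
        assert j[0, 0] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d} = 2/4
        assert j[1, 1] == 1.0
        assert j[0, 1] == 0.0


class TestDegreePreservingRandomize:
    def degrees(self, net):
        d = {}
        for a, b in net.edges:
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
        return sorted(d.values())

    def test_degree_multiset_invariant(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            net = random_gnm_network(15, 35, rng)
            rand = degree_preserving_randomize(net, seed=trial)
            assert self.degrees(rand) == self.degrees(net)
            assert rand.n_edges == net.n_edges
            assert rand.nodes == net.nodes

    def test_star_graph_cannot_be_rewired(self):
        star = make_network([("hub", "a"), ("hub", "b"), ("hub", "c")])
        rand = degree_preserving_randomize(star, n_swaps=500, seed=0)
        assert set(rand.edges) == set(star.edges)

    def test_seeded_determinism_and_actual_rewiring(self):
        rng = np.random.default_rng(9)
        net = random_gnm_network(20, 40, rng)
        r1 = degree_preserving_randomize(net, seed=5)
        r2 = degree_preserving_randomize(net, seed=5)
        assert r1.edges == r2.edges
        assert set(r1.edges) != set(net.edges)  # |E| >= 20: rewiring happens

    def test_weight_multiset_preserved(self):
        net = make_network(
            [("a", "b", 0.9), ("c", "d", 0.8), ("e", "f", 0.7), ("g", "h", 0.6)]
        )
        rand = degree_preserving_randomize(net, n_swaps=100, seed=1)
        assert sorted(rand.edges.values()) == sorted(net.edges.values())


class TestNmiPermutationTest:
    def test_add_one_estimator_consistency_and_bounds(self):
        rng = np.random.default_rng(10)
        net_a = random_gnm_network(20, 45, rng)
        net_b = random_gnm_network(20, 45, rng)
        res = nmi_permutation_test(net_a, net_b, n_perm=19, seed=3)
        assert len(res.null_nmis) == 19
        expected_p = (1 + np.sum(res.null_nmis >= res.observed_nmi)) / 20
        assert res.p_value == pytest.approx(expected_p)
        assert 1 / 20 <= res.p_value <= 1.0

    def test_strong_shared_structure_gets_minimum_p(self):
        """Identical two-clique networks: observed NMI = 1 beats every
        randomized replicate, so p hits the add-one floor 1/(n_perm+1)."""
        left = [f"l{i}" for i in range(6)]
        right = [f"r{i}" for i in range(6)]
        net = make_network(
            clique_edges(left) + clique_edges(right) + [(left[0], right[0])]
        )
        res = nmi_permutation_test(net, net, n_perm=49, seed=0)
        assert res.observed_nmi == 1.0
        assert res.p_value == pytest.approx(1 / 50)

    def test_rejects_bad_n_perm(self):
        net = make_network([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            nmi_permutation_test(net, net, n_perm=0, seed=0)
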