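import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from cohesion_screen.interactome import ReferenceNetwork, ValidationError
from cohesion_screen.pie import (
    DegreeMatchPolicy,
    PieCohesion,
    count_induced_edges,
    degrees_in_reference,
    pie_analysis,
    sample_degree_matched,
)

from conftest import make_net


def from_nx(g) -> ReferenceNetwork:
    return ReferenceNetwork.from_graph(nx.relabel_nodes(g, {i: f"n{i}" for i in g}))


class TestDegrees:
    def test_isolated_nodes_all_zero(self):
        ref = make_net([], nodes=["A", "B", "C"])
        assert degrees_in_reference({"A", "B"}, ref) == [0, 0]

    def test_triangle_plus_pendant(self):
        # triangle A-B-C plus edge C-D: deg(A)=2, deg(C)=3
        ref = make_net([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert degrees_in_reference({"A", "C"}, ref) == [2, 3]

    def test_star_hub(self):
        ref = make_net([("H", f"L{i}") for i in range(5)])
        assert degrees_in_reference({"H"}, ref) == [5]

    def test_absent_node_errors(self):
        ref = make_net([("A", "B")])
        with pytest.raises(ValidationError):
            degrees_in_reference({"A", "zzz"}, ref)


class TestInducedEdges:
    def test_complete_graph_closed_form(self):
        ref = from_nx(nx.complete_graph(4))
        assert count_induced_edges(ref, {"n0", "n1", "n2"}) == 3

    def test_edgeless_set(self):
        ref = make_net([("A", "B")], nodes=["C", "D"])
        assert count_induced_edges(ref, {"C", "D"}) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_scan(self, fixture_network, seed):
        rng = np.random.default_rng(seed)
        subset = set(rng.choice(sorted(fixture_network.nodes), size=4, replace=False))
        brute = sum(
            1
            for a, b in itertools.combinations(sorted(subset), 2)
            if fixture_network.has_edge(a, b)
        )
        assert count_induced_edges(fixture_network, subset) == brute


class TestDegreeMatchedSampling:
    def test_two_isolated_targets(self):
        ref = make_net([("A", "B")], nodes=["I1", "I2", "I3"])
        rng = np.random.default_rng(0)
        s = sample_degree_matched(ref, [0, 0], rng=rng)
        assert len(s) == 2 and s <= {"I1", "I2", "I3"}

    def test_regular_graph_any_subset(self):
        ref = from_nx(nx.cycle_graph(8))  # 2-regular
        rng = np.random.default_rng(1)
        s = sample_degree_matched(ref, [2, 2, 2], rng=rng)
        assert len(s) == 3

    def test_exact_contract_on_every_draw(self, fixture_network):
        target = degrees_in_reference(set("ABF"), fixture_network)  # [1, 2, 3]
        model = PieCohesion(fixture_network, set("ABF"))
        res = model.fit(n_rand=10_000, seed=3, return_samples=True)
        assert res.effective_mode == "exact"
        order = res.sample_node_order
        degs = np.array([fixture_network.degree(n) for n in order])
        for row in res.sample_membership:
            assert sorted(degs[row].tolist()) == target

    def test_selection_uniform_within_degree_class(self, fixture_network):
        """Within a degree class every node should be picked equally often."""
        node_set = set("ABF")  # degrees 2, 3, 1
        model = PieCohesion(fixture_network, node_set)
        n = 10_000
        res = model.fit(n_rand=n, seed=11, return_samples=True)
        freq = res.sample_membership.mean(axis=0)
        degs = {nd: fixture_network.degree(nd) for nd in res.sample_node_order}
        class_sizes = Counter(degs.values())
        target = Counter(degrees_in_reference(node_set, fixture_network))
        for i, nd in enumerate(res.sample_node_order):
            d = degs[nd]
            p = target.get(d, 0) / class_sizes[d]
            se = np.sqrt(p * (1 - p) / n) if 0 < p < 1 else 0.0
            assert abs(freq[i] - p) <= max(3 * se, 1e-12), (nd, freq[i], p)

    def test_infeasible_bin_errors(self):
        ref = make_net([("A", "B")])  # only two degree-1 nodes
        with pytest.raises(ValidationError, match="bin"):
            sample_degree_matched(ref, [1, 1, 1], rng=np.random.default_rng(0))

    def test_thin_degree_class_falls_back_to_binned(self):
        # single degree-2 node forces binned matching
        ref = make_net([("A", "B"), ("B", "C")], nodes=["D", "E"])
        res = PieCohesion(ref, {"B", "A"}).fit(n_rand=50, seed=0)
        assert res.effective_mode == "binned"


def enumerate_null(ref: ReferenceNetwork, node_set):
    """Exhaustive oracle: every exact degree-matched node set and its
    induced edge count, via independent per-class combination product."""
    target = Counter(ref.degree(n) for n in node_set)
    by_degree = {}
    for n in ref.nodes:
        by_degree.setdefault(ref.degree(n), []).append(n)
    class_choices = [
        list(itertools.combinations(sorted(by_degree[d]), k)) for d, k in sorted(target.items())
    ]
    counts = []
    for combo in itertools.product(*class_choices):
        members = [n for group in combo for n in group]
        c = sum(
            1 for a, b in itertools.combinations(members, 2) if ref.has_edge(a, b)
        )
        counts.append(c)
    return np.array(counts)


class TestAgainstExhaustiveEnumeration:
    # fixture seeds chosen so exact matching is feasible (every degree
    # class holds enough candidates) and the null support is non-trivial
    @pytest.mark.parametrize("graph_seed,set_seed", [(0, 4), (1, 1), (2, 3)])
    def test_null_mean_and_tail_within_3se(self, graph_seed, set_seed):
        g = nx.gnm_random_graph(12, 16, seed=graph_seed)
        ref = from_nx(g)
        rng = np.random.default_rng(set_seed)
        node_set = set(rng.choice(sorted(ref.nodes), size=4, replace=False))

        model = PieCohesion(ref, node_set)
        n_rand = 10_000
        res = model.fit(n_rand=n_rand, seed=graph_seed * 100 + set_seed)
        assert res.effective_mode == "exact"
        null = enumerate_null(ref, node_set)

        exact_mean = null.mean()
        se = null.std(ddof=0) / np.sqrt(n_rand)
        assert abs(res.null_mean - exact_mean) <= 3 * se

        obs = res.observed_edges
        exact_tail = (null >= obs).mean()
        tail_se = np.sqrt(exact_tail * (1 - exact_tail) / n_rand)
        mc_tail = (res.null_edge_counts >= obs).mean()
        assert abs(mc_tail - exact_tail) <= max(3 * tail_se, 1e-9)


class TestPieLimits:
    def test_complete_graph_score_one_p_one(self):
        ref = from_nx(nx.complete_graph(8))
        res = pie_analysis(ref, {"n0", "n1", "n2", "n3"}, n_rand=500, seed=0)
        assert res.pie_score == 1.0
        assert res.empirical_p == 1.0
        assert res.null_sd == 0.0

    def test_zero_induced_edges_score_zero(self):
        # two disjoint cliques plus an independent pair of degree-3 nodes
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        ref = from_nx(g)
        node_set = {"n0", "n4"}  # one node from each clique: no mutual edge
        res = pie_analysis(ref, node_set, n_rand=500, seed=0)
        assert res.observed_edges == 0
        assert res.null_mean > 0
        assert res.pie_score == 0.0
        assert res.empirical_p == 1.0

    def test_empirical_p_bounds_and_floor(self, fixture_network):
        res = pie_analysis(fixture_network, set("ABD"), n_rand=200, seed=1)
        assert 1 / 201 <= res.empirical_p <= 1.0

    def test_undefined_score_when_null_mean_zero(self):
        # edgeless reference: observed and null are all zero
        ref = make_net([], nodes=[f"x{i}" for i in range(6)])
        res = pie_analysis(ref, {"x0", "x1"}, n_rand=100, seed=0)
        assert not res.pie_defined
        assert np.isnan(res.pie_score)
        assert res.empirical_p == 1.0


class TestDeterminism:
    def test_same_seed_bit_identical(self, fixture_network):
        a = pie_analysis(fixture_network, set("ABD"), n_rand=2_000, seed=77)
        b = pie_analysis(fixture_network, set("ABD"), n_rand=2_000, seed=77)
        assert np.array_equal(a.null_edge_counts, b.null_edge_counts)
        assert a.to_dict() == b.to_dict()

    def test_summary_mentions_key_fields(self, fixture_network):
        res = pie_analysis(fixture_network, set("ABD"), n_rand=100, seed=0)
        s = res.summary()
        assert "PIE score" in s and "empirical p" in s
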