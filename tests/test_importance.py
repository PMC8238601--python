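"""Composite importance scoring, CRN extraction, baselines and categories."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import typed_from_nx
from oracles import brute_importance

from netpharm import (
    baseline_scores,
    categorize_targets,
    extract_crn,
    importance_scores,
)
from netpharm.networks import REL_CT, ROLE_COMPONENT, ROLE_TARGET, TypedNetwork


class TestCompositeScore:
    def test_path3_values(self, path3):
        s = importance_scores(path3)
        wi = dict(zip(s.nodes, s.wi))
        assert wi["b"] == pytest.approx(1 / 3, abs=1e-15)
        assert wi["a"] == wi["c"] == 0.0
        assert s.wavg == pytest.approx(1 / 9, abs=1e-15)

    def test_star_center(self):
        s = importance_scores(nx.star_graph(3))
        assert s[0] == pytest.approx(0.5, abs=1e-15)
        assert all(s[v] == 0 for v in (1, 2, 3))

    def test_triangle_all_zero(self):
        s = importance_scores(nx.complete_graph(3))
        assert np.all(s.wi == 0)

    @pytest.mark.parametrize("n", range(4, 13))
    def test_star_closed_form(self, n):
        s = importance_scores(nx.star_graph(n - 1))  # n nodes total
        assert s[0] == pytest.approx((n - 2) / n, abs=1e-12)

    def test_product_and_mean_invariants(self):
        g = nx.gnp_random_graph(25, 0.15, seed=7)
        g = g.subgraph(max(nx.connected_components(g), key=len))
        s = importance_scores(nx.Graph(g))
        np.testing.assert_allclose(
            s.wi, s.closeness_factor * s.bridging_factor, atol=1e-15
        )
        assert s.wavg == pytest.approx(float(np.mean(s.wi)), abs=0)
        assert np.all(s.wi >= 0)
        assert np.all((s.bridging_factor >= 0) & (s.bridging_factor <= 1))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_shortest_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        if not nx.is_connected(g):
            g = nx.Graph(g.subgraph(max(nx.connected_components(g), key=len)))
        if g.number_of_nodes() < 3:
            pytest.skip("degenerate draw")
        s = importance_scores(g)
        oracle = brute_importance(g)
        for i, v in enumerate(s.nodes):
            assert s.wi[i] == pytest.approx(oracle[v]["wi"], abs=1e-12)

    def test_matches_networkx_centralities(self):
        # independent cross-check: the two factors equal networkx closeness
        # and pair-normalized betweenness on a mid-size random graph
        g = nx.connected_watts_strogatz_graph(40, 6, 0.3, seed=2)
        s = importance_scores(g)
        n = g.number_of_nodes()
        bc = nx.betweenness_centrality(g, normalized=False)
        cl = nx.closeness_centrality(g)
        for i, v in enumerate(s.nodes):
            assert s.closeness_factor[i] == pytest.approx(cl[v], abs=1e-12)
            assert s.bridging_factor[i] == pytest.approx(
                bc[v] / (n * (n - 1) / 2), abs=1e-12
            )

    def test_relabeling_equivariance(self):
        g = nx.random_regular_graph(3, 10, seed=5)
        s = importance_scores(g)
        mapping = {v: f"node-{(v * 7) % 10}" for v in g.nodes}
        s2 = importance_scores(nx.relabel_nodes(g, mapping))
        a = {mapping[v]: s.wi[i] for i, v in enumerate(s.nodes)}
        b = dict(zip(s2.nodes, s2.wi))
        for v in a:
            assert a[v] == pytest.approx(b[v], abs=1e-12)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            importance_scores(nx.path_graph(2))

    def test_disconnected_rejected_by_default(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        with pytest.raises(ValueError, match="disconnected"):
            importance_scores(g)

    def test_componentwise_mode_scores_components(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        s = importance_scores(g, componentwise=True)
        wi = dict(zip(s.nodes, s.wi))
        # centers bridge their own component's single pair: t=1 of n(n-1)/2=15,
        # closeness over reachable nodes only: (6-1)/2
        assert wi["b"] == pytest.approx((5 / 2) * (1 / 15), abs=1e-12)
        assert wi["a"] == 0.0

    def test_isolated_nodes_dropped_before_scoring(self):
        g = nx.path_graph(3)
        g.add_node("isolated")
        s = importance_scores(g)
        assert s.n == 3 and "isolated" not in s.nodes


class TestCrn:
    def test_path3_center_only(self, path3):
        s = importance_scores(path3)
        crn = extract_crn(path3, s)
        assert crn.kept_nodes == {"b"}
        assert crn.network.n_edges == 0
        assert crn.effective_proteins == {"b"}

    def test_vertex_transitive_graph_empty_crn(self):
        net = typed_from_nx(nx.cycle_graph(6))
        crn = extract_crn(net, importance_scores(net))
        assert crn.kept_nodes == frozenset()

    def test_star_center_kept(self):
        net = typed_from_nx(nx.star_graph(3))
        crn = extract_crn(net, importance_scores(net))
        assert crn.kept_nodes == {"0"} and crn.network.n_edges == 0

    def test_components_excluded_from_effective_proteins(self):
        net = TypedNetwork()
        net.add_node("cmp1", ROLE_COMPONENT)
        for t in "ABCD":
            net.add_node(t, ROLE_TARGET)
            net.add_edge("cmp1", t, REL_CT)
        s = importance_scores(net)
        crn = extract_crn(net, s)
        assert crn.kept_nodes == {"cmp1"}
        assert crn.effective_proteins == frozenset()

    def test_induced_subgraph_keeps_internal_edges(self):
        # two adjacent hubs, each with pendant leaves: both hubs pass and
        # their joining edge must survive in the CRN
        g = nx.Graph([("h1", "h2")])
        for i in range(3):
            g.add_edge("h1", f"a{i}")
            g.add_edge("h2", f"b{i}")
        net = typed_from_nx(g)
        crn = extract_crn(net, importance_scores(net))
        assert crn.kept_nodes == {"h1", "h2"}
        assert crn.network.graph.has_edge("h1", "h2")


class TestBaselines:
    def test_star_center(self):
        net = typed_from_nx(nx.star_graph(3))
        assert baseline_scores(net, "degree").values[0] == 3
        assert baseline_scores(net, "betweenness").values[0] == 3
        assert baseline_scores(net, "clustering").values[0] == 0

    def test_triangle(self):
        net = typed_from_nx(nx.complete_graph(3))
        assert set(baseline_scores(net, "degree").values) == {2}
        assert set(baseline_scores(net, "betweenness").values) == {0}
        assert set(baseline_scores(net, "clustering").values) == {1}

    def test_path_center_betweenness(self, path3):
        s = baseline_scores(path3, "betweenness")
        assert dict(zip(s.nodes, s.values))["b"] == 1

    def test_unknown_method_rejected(self, path3):
        with pytest.raises(ValueError, match="unknown method"):
            baseline_scores(path3, "pagerank")


class TestCategories:
    def test_three_way_split(self):
        cats = categorize_targets({"A", "B", "C"}, {"B", "C", "D"}, set("ABCDE"))
        assert cats.essential_common == {"B", "C"}
        assert cats.component_specific == {"A"}
        assert cats.disease_specific == {"D"}

    def test_disjoint_and_identical(self):
        assert categorize_targets({"A"}, {"B"}, {"A", "B"}).essential_common == frozenset()
        cats = categorize_targets({"A"}, {"A"}, {"A"})
        assert cats.component_specific == cats.disease_specific == frozenset()

    def test_subset_precondition(self):
        with pytest.raises(ValueError):
            categorize_targets({"A"}, {"B"}, {"B"})
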