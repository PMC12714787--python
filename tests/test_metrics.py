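"""Metrics battery: Gini, centralities, assortativities, geodesics.

networkx is the independent cross-check for every standard centrality; the
Gini implementation is checked against an O(n^2) double-loop oracle.
"""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialcircles import (
    Placement,
    SocialCirclesNetwork,
    assortativity_edge,
    assortativity_neighbour_mean,
    betweenness_values,
    closeness_values,
    clustering_values,
    degree_stats,
    eigenvector_values,
    geodesic_stats,
    giant_component,
    gini,
    summarize,
    transitivity,
)

from conftest import brute_force_gini, network_from_nx


def random_connected(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    return nx.convert_node_labels_to_integers(g)


class TestGiantComponent:
    def test_connected_network_is_its_own_giant(self):
        net = network_from_nx(nx.path_graph(5))
        giant = giant_component(net)
        assert giant.edges == net.edges
        assert [p.agent_id for p in giant.placements] == list(range(5))

    def test_largest_component_wins(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.cycle_graph(7))
        giant = giant_component(network_from_nx(g))
        assert len(giant.placements) == 7
        assert {p.agent_id for p in giant.placements} == set(range(3, 10))

    def test_size_tie_broken_by_smallest_id(self):
        g = nx.disjoint_union(nx.cycle_graph(5), nx.cycle_graph(5))
        giant = giant_component(network_from_nx(g))
        assert {p.agent_id for p in giant.placements} == set(range(5))

    def test_isolated_nodes_are_singletons(self):
        net = SocialCirclesNetwork(
            [Placement(i, 0, 0, 0.0) for i in range(4)], {(2, 3)}
        )
        giant = giant_component(net)
        assert {p.agent_id for p in giant.placements} == {2, 3}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            giant_component(SocialCirclesNetwork([], set()))


class TestGini:
    def test_perfect_equality(self):
        assert gini([5, 5, 5, 5]) == 0.0

    def test_two_point_case(self):
        # pair sum 2, n^2 = 4, mean 0.5 -> 2 / (2*4*0.5)
        assert gini([0, 1]) == pytest.approx(0.5)

    def test_all_zero_returns_zero(self):
        assert gini([0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gini([1.0, -0.1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini([])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=200),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_double_loop_oracle(self, values):
        assert gini(values) == pytest.approx(brute_force_gini(values), abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 1e3), min_size=2, max_size=50),
        st.floats(0.001, 1e4),
    )
    @settings(deadline=None, max_examples=60)
    def test_scale_invariance(self, values, c):
        assert gini([c * v for v in values]) == pytest.approx(gini(values), abs=1e-9)


class TestDegreeStats:
    def test_regular_graph(self):
        assert degree_stats(network_from_nx(nx.cycle_graph(3))) == (2.0, 0.0)

    def test_star_on_four_nodes(self):
        mean, g = degree_stats(network_from_nx(nx.star_graph(3)))
        assert mean == pytest.approx(1.5)
        assert g == pytest.approx(0.25)  # brute-force pair sum on (3,1,1,1)


class TestAssortativity:
    @pytest.mark.parametrize("leaves", [3, 5, 9])
    def test_star_is_perfectly_disassortative(self, leaves):
        a = assortativity_edge(network_from_nx(nx.star_graph(leaves)))
        assert a == pytest.approx(-1.0, abs=1e-12)

    def test_regular_graph_flagged_undefined(self):
        assert math.isnan(assortativity_edge(network_from_nx(nx.cycle_graph(6))))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx_definition(self, seed):
        g = random_connected(40, 0.12, seed)
        ours = assortativity_edge(network_from_nx(g))
        theirs = nx.degree_assortativity_coefficient(g)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_neighbour_mean_on_path3(self):
        # degrees (1,2,1) vs neighbour means (2,1,2): perfectly anticorrelated
        a = assortativity_neighbour_mean(network_from_nx(nx.path_graph(3)))
        assert a == pytest.approx(-1.0, abs=1e-12)

    def test_neighbour_mean_undefined_on_complete_graph(self):
        assert math.isnan(assortativity_neighbour_mean(network_from_nx(nx.complete_graph(5))))

    def test_neighbour_mean_requires_min_degree_one(self):
        net = SocialCirclesNetwork(
            [Placement(i, 0, 0, 0.0) for i in range(3)], {(0, 1)}
        )
        with pytest.raises(ValueError):
            assortativity_neighbour_mean(net)


class TestCentralities:
    def test_closeness_on_path3(self):
        clo = closeness_values(network_from_nx(nx.path_graph(3)))
        assert clo[1] == pytest.approx(1.0)
        assert clo[0] == clo[2] == pytest.approx(2 / 3)

    def test_closeness_requires_connected_input(self):
        net = SocialCirclesNetwork(
            [Placement(i, 0, 0, 0.0) for i in range(4)], {(0, 1), (2, 3)}
        )
        with pytest.raises(ValueError, match="giant_component"):
            closeness_values(net)

    def test_betweenness_on_path3(self):
        bet = betweenness_values(network_from_nx(nx.path_graph(3)))
        assert bet[1] == pytest.approx(1.0)
        assert bet[0] == bet[2] == 0.0

    def test_betweenness_zero_on_complete_graph(self):
        assert betweenness_values(network_from_nx(nx.complete_graph(6))).max() == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_betweenness_matches_networkx(self, seed):
        g = random_connected(30, 0.15, seed)
        ours = betweenness_values(network_from_nx(g))
        theirs = nx.betweenness_centrality(g, normalized=True)
        assert ours == pytest.approx([theirs[v] for v in sorted(g)], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_closeness_matches_networkx(self, seed):
        g = random_connected(30, 0.15, seed)
        ours = closeness_values(network_from_nx(g))
        theirs = nx.closeness_centrality(g)
        assert ours == pytest.approx([theirs[v] for v in sorted(g)], abs=1e-9)

    def test_eigenvector_star_closed_form(self):
        eig = eigenvector_values(network_from_nx(nx.star_graph(3)))
        assert eig[0] == pytest.approx(math.sqrt(1 / 2), abs=1e-9)
        assert eig[1:] == pytest.approx([math.sqrt(1 / 6)] * 3, abs=1e-9)

    def test_eigenvector_regular_graph_uniform(self):
        eig = eigenvector_values(network_from_nx(nx.cycle_graph(8)))
        assert gini(eig) == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(eig) == pytest.approx(1.0)


class TestClusteringTransitivity:
    def test_triangle(self):
        net = network_from_nx(nx.complete_graph(3))
        assert clustering_values(net).tolist() == [1.0, 1.0, 1.0]
        assert transitivity(net) == 1.0

    def test_star_has_no_triangles(self):
        net = network_from_nx(nx.star_graph(4))
        assert clustering_values(net).max() == 0.0
        assert transitivity(net) == 0.0

    def test_no_triples_flagged(self):
        net = SocialCirclesNetwork(
            [Placement(i, 0, 0, 0.0) for i in range(2)], {(0, 1)}
        )
        assert math.isnan(transitivity(net))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx(self, seed):
        g = random_connected(30, 0.2, seed)
        net = network_from_nx(g)
        theirs = nx.clustering(g)
        assert clustering_values(net) == pytest.approx(
            [theirs[v] for v in sorted(g)], abs=1e-9
        )
        assert transitivity(net) == pytest.approx(nx.transitivity(g), abs=1e-9)


class TestGeodesics:
    def test_complete_graph(self):
        assert geodesic_stats(network_from_nx(nx.complete_graph(5))) == (1.0, 0.0, 1)

    def test_path3(self):
        mean, g, diam = geodesic_stats(network_from_nx(nx.path_graph(3)))
        assert mean == pytest.approx(4 / 3)  # pair distances {1, 1, 2}
        assert diam == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bfs_oracle(self, seed):
        g = random_connected(30, 0.15, seed)
        mean, gcoef, diam = geodesic_stats(network_from_nx(g))
        # exhaustive BFS from every node via networkx
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        pairs = [
            lengths[u][v] for u in g for v in g if u < v
        ]
        assert mean == pytest.approx(np.mean(pairs), abs=1e-9)
        assert gcoef == pytest.approx(brute_force_gini(pairs), abs=1e-9)
        assert diam == max(pairs)


class TestSummarize:
    def test_complete_graph_k5(self):
        s = summarize(network_from_nx(nx.complete_graph(5)))
        assert s.n_giant == 5 and s.edges == 5 * 4 // 2
        assert s.density == 1.0 and s.degree_mean == 4.0
        assert s.transitivity == 1.0
        assert (s.geodesic_mean, s.geodesic_gini, s.diameter) == (1.0, 0.0, 1)
        for field in ("degree_gini", "closeness_gini", "betweenness_gini",
                      "eigenvector_gini", "clustering_gini"):
            assert getattr(s, field) == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(s.assortativity_edge)
        assert math.isnan(s.assortativity_neighbour_mean)

    @pytest.mark.parametrize("seed", range(3))
    def test_internal_consistency_with_standalone_ops(self, seed):
        g = random_connected(40, 0.12, seed)
        net = network_from_nx(g)
        s = summarize(net)
        giant = giant_component(net)
        mean, dg = degree_stats(giant)
        assert (s.degree_mean, s.degree_gini) == (mean, dg)
        assert s.assortativity_edge == pytest.approx(assortativity_edge(giant))
        clo = closeness_values(giant)
        assert (s.closeness_mean, s.closeness_gini) == (
            pytest.approx(clo.mean()), pytest.approx(gini(clo)))
        bet = betweenness_values(giant)
        assert s.betweenness_mean == pytest.approx(bet.mean())
        assert s.transitivity == pytest.approx(transitivity(giant))
        assert (s.geodesic_mean, s.geodesic_gini, s.diameter) == geodesic_stats(giant)
        # density ties edges and node count together exactly
        assert s.density * s.n_giant * (s.n_giant - 1) / 2 == pytest.approx(s.edges)

    def test_row_serialization_is_stable(self):
        s = summarize(network_from_nx(nx.complete_graph(4)))
        row = s.to_row()
        assert len(row.split(",")) == len(s.COLUMNS)
        assert row.split(",")[0] == "4"
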