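"""Metabolic-network construction, centrality, and conservation overlays."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from helpers import brute_force_betweenness

from metafunc.netmap import (
    DEFAULT_COMPOUND_BLACKLIST,
    betweenness,
    build_metabolic_network,
    conservation_vs_expression,
    overlay_expression,
    top_n_subnetwork,
)


def _reactions(rows):
    return pd.DataFrame(rows, columns=["ec", "role", "compound"])


class TestBuildMetabolicNetwork:
    def test_shared_compound_connects_enzymes(self):
        net = build_metabolic_network(
            _reactions([("1.1.1.1", "product", "X"), ("2.2.2.2", "substrate", "X")])
        )
        assert net.has_edge("1.1.1.1", "2.2.2.2")
        assert net["1.1.1.1"]["2.2.2.2"]["compounds"] == {"X"}

    def test_blacklisted_compound_never_connects(self):
        net = build_metabolic_network(
            _reactions([("1.1.1.1", "product", "ATP"), ("2.2.2.2", "substrate", "ATP")])
        )
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2

    def test_three_sharers_form_a_triangle(self):
        net = build_metabolic_network(
            _reactions([(ec, "substrate", "X") for ec in ("1.1.1.1", "2.2.2.2", "3.3.3.3")])
        )
        assert net.number_of_edges() == 3

    def test_shared_compound_labels_union(self):
        net = build_metabolic_network(
            _reactions(
                [
                    ("1.1.1.1", "product", "X"),
                    ("2.2.2.2", "substrate", "X"),
                    ("1.1.1.1", "product", "Y"),
                    ("2.2.2.2", "substrate", "Y"),
                ]
            )
        )
        assert net["1.1.1.1"]["2.2.2.2"]["compounds"] == {"X", "Y"}

    def test_edge_count_monotone_in_blacklist(self):
        rows = [
            ("1.1.1.1", "product", "X"),
            ("2.2.2.2", "substrate", "X"),
            ("2.2.2.2", "product", "Y"),
            ("3.3.3.3", "substrate", "Y"),
        ]
        for smaller, larger in [(frozenset(), {"X"}), ({"X"}, {"X", "Y"})]:
            n_small = build_metabolic_network(_reactions(rows), smaller).number_of_edges()
            n_large = build_metabolic_network(_reactions(rows), larger).number_of_edges()
            assert n_large <= n_small


class TestOverlay:
    def test_expression_attached_and_absent_is_zero(self):
        net = build_metabolic_network(
            _reactions([("1.1.1.1", "product", "X"), ("2.2.2.2", "substrate", "X")])
        )
        overlay_expression(net, {"1.1.1.1": 12.5})
        assert net.nodes["1.1.1.1"]["expression"] == 12.5
        assert net.nodes["2.2.2.2"]["expression"] == 0.0

    def test_overlay_is_idempotent(self):
        net = nx.Graph()
        net.add_node("1.1.1.1")
        overlay_expression(net, {"1.1.1.1": 3.0})
        overlay_expression(net, {"1.1.1.1": 3.0})
        assert net.nodes["1.1.1.1"]["expression"] == 3.0


class TestTopN:
    @staticmethod
    def _net(expr):
        net = nx.path_graph(sorted(expr))
        overlay_expression(net, expr)
        return net

    def test_n_at_least_node_count_returns_whole_network(self):
        net = self._net({"a": 1.0, "b": 2.0, "c": 3.0})
        assert set(top_n_subnetwork(net, 10).nodes) == {"a", "b", "c"}

    def test_n_one_is_single_highest_node(self):
        sub = top_n_subnetwork(self._net({"a": 1.0, "b": 9.0, "c": 3.0}), 1)
        assert set(sub.nodes) == {"b"} and sub.number_of_edges() == 0

    def test_induced_subgraph_on_known_ranks(self):
        expr = {"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0}
        sub = top_n_subnetwork(self._net(expr), 3)
        assert set(sub.nodes) == {"a", "b", "c"}
        assert sub.has_edge("a", "b") and sub.has_edge("b", "c")

    def test_nested_for_increasing_n(self):
        expr = {f"n{i}": float(i % 7) for i in range(12)}
        net = self._net(expr)
        for n1, n2 in [(1, 4), (4, 8), (8, 12)]:
            assert set(top_n_subnetwork(net, n1)) <= set(top_n_subnetwork(net, n2))


class TestBetweenness:
    def test_path_center_is_one(self):
        assert betweenness(nx.path_graph(["a", "b", "c"])) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_is_one_leaves_zero(self):
        g = nx.star_graph(4)
        values = betweenness(g)
        assert values[0] == pytest.approx(1.0)
        assert all(values[leaf] == 0.0 for leaf in range(1, 5))

    def test_components_smaller_than_three_score_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        assert betweenness(g) == {"a": 0.0, "b": 0.0, "c": 0.0}

    def test_matches_brute_force_enumeration(self):
        """Brandes accumulation equals exhaustive path counting to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.6)), seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            ref = brute_force_betweenness(list(g.edges), list(g.nodes))
            mine = betweenness(g)
            for v in g.nodes:
                assert mine[v] == pytest.approx(ref[v], abs=1e-9)


class TestConservationVsExpression:
    @staticmethod
    def _ppi(genes):
        g = nx.Graph()
        for a, b in zip(genes, genes[1:]):
            g.add_edge(a, b)
        return g

    def test_conserved_silent_and_rare_expressed_flags(self):
        genes = [f"g{i}" for i in range(8)]
        ppi = self._ppi(genes)
        conservation = {g: c for g, c in zip(genes, [1000, 900, 800, 500, 400, 100, 50, 20])}
        expression = {g: e for g, e in zip(genes, [0.0, 5.0, 50.0, 20.0, 30.0, 10.0, 900.0, 2.0])}
        table = conservation_vs_expression(ppi, conservation, expression)
        assert bool(table.loc["g0", "conserved_silent"])  # 1000 genomes, silent
        assert bool(table.loc["g6", "rare_expressed"])  # 50 genomes, top expression
        assert not table.loc["g2", ["conserved_silent", "rare_expressed"]].any()

    def test_empty_ortholog_table_flags_nothing_conserved_silent(self):
        ppi = self._ppi(["a", "b", "c", "d"])
        table = conservation_vs_expression(ppi, {}, {"a": 5.0, "b": 1.0, "c": 0.0, "d": 9.0})
        assert table["conservation"].eq(0).all()
        assert not table["conserved_silent"].any()
        assert not table["rare_expressed"].any()

    def test_conservation_cannot_exceed_genome_total(self):
        ppi = self._ppi(["a", "b"])
        with pytest.raises(ValueError):
            conservation_vs_expression(ppi, {"a": 2000}, {})

    def test_expression_rank_is_one_for_highest(self):
        ppi = self._ppi(["a", "b", "c"])
        table = conservation_vs_expression(ppi, {}, {"a": 1.0, "b": 7.0, "c": 3.0})
        assert table.loc["b", "expression_rank"] == 1


def test_default_blacklist_contains_currency_metabolites():
    assert {"ATP", "H2O", "NADH"} <= set(DEFAULT_COMPOUND_BLACKLIST)
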