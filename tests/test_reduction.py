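"""Unit and property tests for the reduction algorithms.

Every algorithmic route is checked against an independent oracle:
per-node reachability (networkx) for the closure, networkx's own
transitive reduction for acyclic graphs, and exhaustive simple-path
enumeration for the minimax uncertainties and the weighted reduction.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trnet
from trnet.graph_model import NO_EDGE
from trnet.reduction import CyclicGraphError

from conftest import edge_set, random_weighted


def to_nx(g):
    gx = nx.DiGraph()
    gx.add_nodes_from(range(g.n))
    mask = g.edge_mask if isinstance(g, trnet.WeightedDigraph) else g.adjacency
    gx.add_edges_from(zip(*np.nonzero(mask)))
    return gx


def definition_tr_weighted(g, thresholds=trnet.Thresholds()):
    """Oracle: keep {w <= t_low} plus {w < t_up and w == h} with h from
    exhaustive path enumeration."""
    h = trnet.brute_force_h(g).values
    keep = g.edge_mask & (
        (g.weights <= thresholds.low)
        | ((g.weights < thresholds.up) & (g.weights == h))
    )
    return trnet.WeightedDigraph(
        list(g.node_labels), np.where(keep, g.weights, NO_EDGE)
    )


class TestPathUncertainty:
    def test_chain_maximum(self, chain_with_shortcuts):
        assert trnet.path_uncertainty(chain_with_shortcuts, ["1", "2", "3"]) == 0.3

    def test_single_edge_is_its_weight(self, chain_with_shortcuts):
        assert trnet.path_uncertainty(chain_with_shortcuts, ["1", "4"]) == 0.5

    def test_protected_diamond_long_path(self, protected_diamond):
        assert trnet.path_uncertainty(protected_diamond, ["d", "b", "a", "c"]) == 0.3

    def test_missing_edge_names_pair(self, chain_with_shortcuts):
        with pytest.raises(ValueError, match=r"\(4, 1\)"):
            trnet.path_uncertainty(chain_with_shortcuts, ["1", "4", "1"])


class TestTransitiveClosure:
    def test_chain_gains_shortcut(self):
        g = trnet.UnweightedDigraph.from_edges([("a", "b"), ("b", "c")])
        assert edge_set(trnet.transitive_closure(g)) == {
            ("a", "b"), ("b", "c"), ("a", "c")
        }

    def test_edgeless_fixed_point(self):
        g = trnet.UnweightedDigraph(["a", "b"], np.zeros((2, 2), bool))
        assert trnet.transitive_closure(g) == g

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reachability_oracle(self, seed):
        g = trnet.random_digraph(8, "erdos_renyi", 0.25, seed=seed)
        closure = trnet.transitive_closure(g)
        gx = to_nx(g)
        for i in range(g.n):
            # reachable by a path of length >= 1: one step, then descendants
            reach = set()
            for s in gx.successors(i):
                reach |= {s} | nx.descendants(gx, s)
            for j in range(g.n):
                assert bool(closure.adjacency[i, j]) == (j in reach)


class TestUnweightedAcyclic:
    def test_triangle_drops_shortcut(self):
        g = trnet.UnweightedDigraph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert edge_set(trnet.tr_unweighted_acyclic(g)) == {("a", "b"), ("b", "c")}

    def test_single_edge_unchanged(self):
        g = trnet.UnweightedDigraph.from_edges([("a", "b")])
        assert trnet.tr_unweighted_acyclic(g) == g

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_library_reduction_on_dags(self, seed):
        g = trnet.random_digraph(7, "dag", 0.4, seed=seed)
        ours = trnet.tr_unweighted_acyclic(g)
        ref = nx.transitive_reduction(to_nx(g))
        assert {tuple(map(int, e)) for e in ref.edges()} == {
            (g.index(u), g.index(v)) for u, v in ours.edges()
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_is_minimal_among_closure_preserving_subgraphs(self, seed):
        """Uniqueness: no strictly smaller edge subset keeps the closure."""
        g = trnet.random_digraph(5, "dag", 0.5, seed=seed)
        ours = trnet.tr_unweighted_acyclic(g)
        closure = trnet.transitive_closure(g)
        edges = list(zip(*np.nonzero(g.adjacency)))
        best = None
        for r in range(len(edges) + 1):
            for subset in itertools.combinations(edges, r):
                adj = np.zeros_like(g.adjacency)
                for i, j in subset:
                    adj[i, j] = True
                sub = trnet.UnweightedDigraph(list(g.node_labels), adj)
                if trnet.transitive_closure(sub) == closure:
                    best = sub
                    break
            if best is not None:
                break
        assert best == ours

    def test_rejects_cycles(self):
        g = trnet.UnweightedDigraph.from_edges([("a", "b"), ("b", "a")])
        with pytest.raises(CyclicGraphError, match="tr_unweighted"):
            trnet.tr_unweighted_acyclic(g)

    def test_rejects_self_loops(self):
        g = trnet.UnweightedDigraph.from_edges([("a", "a")])
        with pytest.raises(CyclicGraphError):
            trnet.tr_unweighted_acyclic(g)


class TestUnweightedCyclic:
    def test_cycle_edge_survives_despite_long_walk(self):
        # walk a,b,a,c is longer than one edge but revisits a: not a detour
        g = trnet.UnweightedDigraph.from_edges([("a", "b"), ("b", "a"), ("a", "c")])
        assert trnet.tr_unweighted(g) == g

    def test_dag_input_equals_acyclic_routine(self):
        g = trnet.random_digraph(8, "dag", 0.4, seed=11)
        assert trnet.tr_unweighted(g) == trnet.tr_unweighted_acyclic(g)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_closure_preserved_on_cyclic_graphs(self, seed):
        g = trnet.random_digraph(8, "erdos_renyi", 0.25, seed=seed)
        assert trnet.transitive_closure(trnet.tr_unweighted(g)) == (
            trnet.transitive_closure(g)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed):
        g = trnet.random_digraph(8, "erdos_renyi", 0.3, seed=seed)
        once = trnet.tr_unweighted(g)
        assert trnet.tr_unweighted(once) == once


class TestMinimaxUncertainty:
    def test_chain_shortcuts_marked(self, chain_with_shortcuts):
        um = trnet.minimax_uncertainty(chain_with_shortcuts)
        g = chain_with_shortcuts
        assert um.values[g.index("1"), g.index("4")] == 0.3
        assert um.values[g.index("2"), g.index("4")] == 0.3
        assert um.deleted[g.index("1"), g.index("4")]
        assert um.deleted[g.index("2"), g.index("4")]

    def test_single_edge_no_markers(self):
        g = trnet.WeightedDigraph.from_edges([("a", "b", 0.4)])
        um = trnet.minimax_uncertainty(g)
        assert um.values[0, 1] == 0.4
        assert not um.deleted.any()

    def test_lower_threshold_hides_better_path(self, protected_diamond):
        g = protected_diamond
        um = trnet.minimax_uncertainty(g, trnet.Thresholds(t_low=0.5))
        d, c, b = g.index("d"), g.index("c"), g.index("b")
        assert um.values[d, c] == 0.5  # via protected (b,c), not 0.3
        assert um.deleted[d, c]
        assert um.values[b, c] == 0.5 and not um.deleted[b, c]

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_brute_force_enumeration(self, seed):
        g = random_weighted(7, 0.35, seed=seed)
        um = trnet.minimax_uncertainty(g)
        bf = trnet.brute_force_h(g)
        assert np.array_equal(um.values, bf.values)
        assert np.array_equal(um.deleted, bf.deleted)

    def test_invalid_permutation_rejected(self, chain_with_shortcuts):
        with pytest.raises(ValueError):
            trnet.minimax_uncertainty(chain_with_shortcuts, node_order=[0, 0, 1, 2])

    @given(st.integers(0, 2**31 - 1), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_final_values_independent_of_pivot_order(self, seed, order_seed):
        g = random_weighted(7, 0.35, seed=seed)
        order = np.random.default_rng(order_seed).permutation(g.n)
        a = trnet.minimax_uncertainty(g)
        b = trnet.minimax_uncertainty(g, node_order=list(order))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.deleted, b.deleted)

    @pytest.mark.parametrize("seed", range(10))
    def test_h_bounded_by_edge_weight(self, seed):
        g = random_weighted(8, 0.3, seed=seed)
        h = trnet.minimax_uncertainty(g).values
        mask = g.edge_mask
        assert (h[mask] <= g.weights[mask]).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_an_edge_never_raises_h(self, seed):
        g = random_weighted(7, 0.3, seed=seed)
        h0 = trnet.minimax_uncertainty(g).values
        rng = np.random.default_rng(seed + 500)
        free = list(zip(*np.nonzero(~g.edge_mask)))
        free = [(i, j) for i, j in free if i != j]
        if not free:
            return
        i, j = free[rng.integers(len(free))]
        g2 = g.copy()
        g2.weights[i, j] = rng.random()
        h1 = trnet.minimax_uncertainty(g2).values
        assert (h1 <= h0).all()


class TestWeightedReduction:
    def test_chain_shortcuts_removed(self, chain_with_shortcuts):
        r = trnet.tr_weighted(chain_with_shortcuts)
        assert edge_set(r) == {("1", "2"), ("2", "3"), ("3", "4")}
        # kept edges keep their original weights
        assert r.weight("2", "3") == 0.3

    def test_equal_weights_identity(self):
        topo = trnet.random_digraph(8, "erdos_renyi", 0.4, seed=9)
        g = trnet.assign_weights(topo, "fixed", value=0.5)
        assert trnet.tr_weighted(g) == g

    def test_threshold_protection_decides_removal(self, protected_diamond):
        t = trnet.Thresholds(t_low=0.5)
        r = trnet.tr_weighted(protected_diamond, t)
        assert ("d", "c") not in edge_set(r)  # w=0.6 > t_low: removed
        g2 = protected_diamond.copy()
        g2.weights[g2.index("d"), g2.index("c")] = 0.4
        r2 = trnet.tr_weighted(g2, t)
        assert ("d", "c") in edge_set(r2)  # w=0.4 <= t_low: protected

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_definition_oracle_random_thresholds(self, seed):
        g = random_weighted(7, 0.35, seed=seed)
        rng = np.random.default_rng(seed + 900)
        lo, up = sorted(rng.random(2))
        for t in (trnet.Thresholds(), trnet.Thresholds(lo, up),
                  trnet.Thresholds(t_low=lo), trnet.Thresholds(t_up=up)):
            assert trnet.tr_weighted(g, t) == definition_tr_weighted(g, t)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed):
        g = random_weighted(8, 0.3, seed=seed)
        once = trnet.tr_weighted(g)
        assert trnet.tr_weighted(once) == once

    def test_self_loop_cut_only_by_more_certain_cycle(self):
        g = trnet.WeightedDigraph.from_edges(
            [("a", "a", 0.6), ("a", "b", 0.2), ("b", "a", 0.3)]
        )
        r = trnet.tr_weighted(g)
        assert ("a", "a") not in edge_set(r)  # cycle a->b->a at 0.3 beats 0.6
        g2 = trnet.WeightedDigraph.from_edges(
            [("a", "a", 0.1), ("a", "b", 0.2), ("b", "a", 0.3)]
        )
        assert ("a", "a") in edge_set(trnet.tr_weighted(g2))


class TestUpperThreshold:
    def test_disabled_is_identity(self, chain_with_shortcuts):
        assert trnet.apply_upper_threshold(chain_with_shortcuts, NO_EDGE) == (
            chain_with_shortcuts
        )

    def test_below_min_empties_graph(self, chain_with_shortcuts):
        assert trnet.apply_upper_threshold(chain_with_shortcuts, 0.05).n_edges == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_commutes_with_weighted_reduction(self, seed):
        g = random_weighted(7, 0.35, seed=seed)
        t_up = float(np.random.default_rng(seed + 77).random())
        t = trnet.Thresholds(t_up=t_up)
        via_pre = trnet.tr_weighted(trnet.apply_upper_threshold(g, t_up), t)
        via_post = trnet.apply_upper_threshold(trnet.tr_weighted(g, t), t_up)
        assert via_pre == via_post


def test_brute_force_size_guard():
    g = trnet.random_digraph(13, "dag", 0.1, seed=0).as_weighted()
    with pytest.raises(ValueError, match="n=13"):
        trnet.brute_force_h(g)


def test_brute_force_two_node_graph():
    g = trnet.WeightedDigraph.from_edges([("a", "b", 0.7)])
    h = trnet.brute_force_h(g).values
    assert h[0, 1] == 0.7 and h[1, 0] == NO_EDGE
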