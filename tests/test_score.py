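"""Weighted s-core decomposition, its oracle, k-core and rank correlation."""

from __future__ import annotations

import itertools

import igraph as ig
import networkx as nx
import numpy as np
import pytest

from ballastnet import (DecompositionParams, ShellAssignment, core_summaries,
                        k_core_decompose, kendall_tau, s_core_decompose,
                        s_core_decompose_oracle, weighted_out_degree)
from conftest import random_weighted_digraph

P11 = DecompositionParams(alpha=1.0, beta=1.0)


def digraph(edges):
    G = nx.DiGraph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=w)
    return G


def two_cycle_plus_isolated():
    G = digraph([("A", "B", 1.0), ("B", "A", 1.0)])
    G.add_node("C")
    return G


class TestWeightedOutDegree:
    def test_no_out_edges_is_zero(self):
        G = two_cycle_plus_isolated()
        assert weighted_out_degree(G, "C", P11) == 0.0

    def test_closed_form(self):
        # d = 4, sum w = 0.04 -> sqrt(0.16) = 0.4
        G = digraph([("X", t, 0.01) for t in "ABCD"])
        assert weighted_out_degree(G, "X", P11) == pytest.approx(0.4, rel=1e-12)

    def test_uniform_weights_identity(self):
        # with all weights w: d' = d * sqrt(w)
        rng = np.random.default_rng(2)
        w = 0.37
        G = random_weighted_digraph(rng, n_nodes=10, max_edges=40, weight=w)
        for n in G.nodes:
            d = G.out_degree(n)
            assert weighted_out_degree(G, n, P11) == pytest.approx(
                d * np.sqrt(w), rel=1e-9)

    def test_beta_zero_reduces_to_out_degree(self):
        G = digraph([("X", "A", 0.2), ("X", "B", 0.9), ("A", "X", 0.1)])
        p = DecompositionParams(alpha=1.0, beta=0.0)
        assert weighted_out_degree(G, "X", p) == 2.0

    def test_absent_node_rejected(self):
        with pytest.raises(KeyError):
            weighted_out_degree(nx.DiGraph(), "Z", P11)


class TestSCoreDecompose:
    def test_two_cycle_plus_sink(self):
        shells = s_core_decompose(two_cycle_plus_isolated(), P11)
        assert shells.shell_of == {"C": 0, "A": 1, "B": 1}
        assert shells.thresholds == (0.0, 1.0)

    def test_complete_symmetric_digraph_is_single_shell(self):
        G = digraph([(u, v, 0.5) for u, v in itertools.permutations(range(5), 2)])
        shells = s_core_decompose(G, P11)
        assert shells.n_shells == 1
        assert set(shells.shell_of.values()) == {0}

    def test_empty_graph(self):
        shells = s_core_decompose(nx.DiGraph(), P11)
        assert shells.shell_of == {} and shells.thresholds == ()

    def test_single_node(self):
        G = nx.DiGraph()
        G.add_node("A")
        assert s_core_decompose(G, P11).shell_of == {"A": 0}

    def test_deepest_core_respects_its_threshold(self):
        rng = np.random.default_rng(7)
        G = random_weighted_digraph(rng, n_nodes=12, max_edges=40)
        shells = s_core_decompose(G, P11)
        k = shells.n_shells - 1
        core = shells.core_members(k)
        H = G.subgraph(core)
        for n in core:
            assert weighted_out_degree(H, n, P11) >= shells.thresholds[k] - 1e-12

    def test_matches_one_at_a_time_oracle_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            G = random_weighted_digraph(rng, max_nodes=10, max_edges=25)
            fast = s_core_decompose(G, P11)
            ref = s_core_decompose_oracle(G, P11)
            assert fast.shell_of == ref.shell_of
            assert fast.thresholds == pytest.approx(ref.thresholds, abs=1e-9)

    def test_order_independence(self):
        rng = np.random.default_rng(13)
        G = random_weighted_digraph(rng, n_nodes=10, max_edges=30)
        base = s_core_decompose(G, P11)
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(list(G.nodes))
            H = nx.DiGraph()
            H.add_nodes_from(perm)
            edges = list(G.edges(data=True))
            np.random.default_rng(seed).shuffle(edges)
            for u, v, d in edges:
                H.add_edge(u, v, **d)
            assert s_core_decompose(H, P11).shell_of == base.shell_of

    def test_edge_removal_never_raises_a_nodes_threshold(self):
        """Deleting an edge can only weaken a node's position: the peeling
        threshold at which it falls never increases (checked against the
        one-at-a-time oracle on small graphs)."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            G = random_weighted_digraph(rng, max_nodes=8, max_edges=18)
            if G.number_of_edges() == 0:
                continue
            before = s_core_decompose_oracle(G, P11)
            thr_before = {n: before.thresholds[k] for n, k in before.shell_of.items()}
            edges = list(G.edges)
            u, v = edges[int(rng.integers(len(edges)))]
            H = G.copy()
            H.remove_edge(u, v)
            after = s_core_decompose_oracle(H, P11)
            for n, k in after.shell_of.items():
                assert after.thresholds[k] <= thr_before[n] + 1e-12


class TestKCore:
    def test_tree_has_max_shell_threshold_one(self):
        G = nx.DiGraph()
        G.add_edges_from([("R", "A"), ("R", "B"), ("A", "C"), ("A", "D")],
                         weight=1.0)
        shells = k_core_decompose(G)
        assert max(shells.thresholds) <= 1.0

    def test_empty_graph(self):
        assert k_core_decompose(nx.DiGraph()).shell_of == {}

    def test_uniform_weight_shell_ordering_matches_k_core(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            G = random_weighted_digraph(rng, max_nodes=12, max_edges=30,
                                        weight=0.41)
            s_shells = s_core_decompose(G, P11)
            k_shells = k_core_decompose(G)
            assert s_shells.shell_of == k_shells.shell_of

    def test_thresholds_match_igraph_out_coreness(self):
        """The peeling threshold of each node's shell equals its classic
        out-degree core number, cross-checked against igraph."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            G = random_weighted_digraph(rng, max_nodes=12, max_edges=30)
            nodes = sorted(G.nodes)
            idx = {n: i for i, n in enumerate(nodes)}
            g = ig.Graph(n=len(nodes),
                         edges=[(idx[u], idx[v]) for u, v in G.edges],
                         directed=True)
            coreness = g.coreness(mode="out")
            shells = k_core_decompose(G)
            for n in nodes:
                assert shells.thresholds[shells.shell_of[n]] == coreness[idx[n]]


def brute_force_tau_b(a, b):
    """Tie-corrected Kendall tau via explicit pair counting."""
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (conc - disc) / denom


class TestKendallTau:
    def test_identical_rankings(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            a = rng.integers(0, 5, n).astype(float)
            b = rng.integers(0, 5, n).astype(float)
            if len(set(a)) == 1 or len(set(b)) == 1:
                continue  # tau-b undefined
            assert kendall_tau(a, b) == pytest.approx(brute_force_tau_b(a, b),
                                                      rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])


class TestCoreSummaries:
    def test_single_shell_graph(self):
        G = digraph([(u, v, 0.5) for u, v in itertools.permutations(range(4), 2)])
        shells = s_core_decompose(G, P11)
        table = core_summaries(G, shells, P11)
        assert len(table) == 1
        assert table.loc[0, "shell_size"] == 4
        assert table.loc[0, "core_mean_out_degree"] == 3.0

    def test_two_cycle_example_hand_arithmetic(self):
        G = two_cycle_plus_isolated()
        table = core_summaries(G, s_core_decompose(G, P11), P11)
        # shell 0 = {C} (out-degree 0), shell 1 = {A, B} (out-degree 1 each)
        assert table["shell_mean_out_degree"].tolist() == [0.0, 1.0]
        assert table["core_size"].tolist() == [3, 2]
        # core 0 mean degree: (0 + 1 + 1)/3
        assert table.loc[0, "core_mean_out_degree"] == pytest.approx(2 / 3)

    def test_core_sizes_non_increasing(self):
        rng = np.random.default_rng(8)
        G = random_weighted_digraph(rng, n_nodes=15, max_edges=60)
        table = core_summaries(G, s_core_decompose(G, P11), P11)
        sizes = table["core_size"].tolist()
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_mismatched_assignment_rejected(self):
        G = two_cycle_plus_isolated()
        other = ShellAssignment({"A": 0, "B": 0}, (0.5,))
        with pytest.raises(ValueError):
            core_summaries(G, other, P11)


class TestShellAssignmentInvariants:
    def test_contiguity_enforced(self):
        with pytest.raises(ValueError):
            ShellAssignment({"A": 0, "B": 2}, (0.0, 1.0, 2.0))

    def test_threshold_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            ShellAssignment({"A": 0, "B": 1}, (1.0, 0.5))

    def test_nestedness_of_cores(self):
        rng = np.random.default_rng(19)
        G = random_weighted_digraph(rng, n_nodes=14, max_edges=60)
        shells = s_core_decompose(G, P11)
        for k in range(shells.n_shells - 1):
            assert shells.core_members(k + 1) <= shells.core_members(k)
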