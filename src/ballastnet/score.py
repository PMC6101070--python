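"""Weighted s-core / s-shell decomposition of the invasion network.

The classic k-core of a directed graph (by out-degree) is the maximal
subgraph in which every node keeps out-degree >= k; peeling the graph at
successive k yields nested cores, and the k-shell is what the (k+1)-core
loses.  Deep shells mark nodes that are both well connected and centrally
placed — in an invasion network, ports that can efficiently relay an
established invader onward (stepping stones).

The s-core generalises this to weighted graphs through a combined
out-degree

    d'_i = [ d_i^alpha * (sum_j w_ij)^beta ]^(1/(alpha+beta))

with ``d_i`` the out-degree and the sum over outgoing edge weights
(alpha = beta = 1 by default, giving ``sqrt(d * sum w)``).  Peeling runs
at real-valued thresholds: the first threshold s_0 is the minimum d'
over all nodes; every node at or below the current threshold is removed
(recomputing d' on the remaining subgraph until no removals occur), the
removed set is the current shell, and the survivors' minimum d' becomes
the next, strictly larger, threshold.  Shell indices are the ordinal
rank 0, 1, 2, ... of those thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

#: Absolute tolerance for the "d' <= threshold" comparison during peeling.
PEEL_TOL = 1e-12

__all__ = [
    "DecompositionParams", "ShellAssignment",
    "weighted_out_degree", "s_core_decompose", "s_core_decompose_oracle",
    "k_core_decompose", "kendall_tau", "core_summaries",
]


@dataclass(frozen=True)
class DecompositionParams:
    """Exponents of the combined degree: ``alpha`` on out-degree, ``beta``
    on the outgoing weight sum.  ``alpha = 1, beta = 0`` recovers the
    unweighted k-core."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("need alpha >= 0, beta >= 0, alpha + beta > 0")


@dataclass(frozen=True)
class ShellAssignment:
    """Result of a core decomposition.

    ``shell_of`` maps each node to its shell index ``k`` (0-based,
    contiguous, every shell non-empty); ``thresholds[k]`` is the peeling
    threshold ``s_k`` at which shell ``k`` was removed, strictly
    increasing in ``k``.
    """

    shell_of: dict[Hashable, int]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shell_of:
            ks = set(self.shell_of.values())
            if ks != set(range(len(self.thresholds))):
                raise ValueError("shell indices must be contiguous 0..K "
                                 "with every shell non-empty")
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        elif self.thresholds:
            raise ValueError("empty assignment cannot carry thresholds")

    @property
    def n_shells(self) -> int:
        return len(self.thresholds)

    def shell_members(self, k: int) -> set:
        return {n for n, s in self.shell_of.items() if s == k}

    def core_members(self, k: int) -> set:
        """Nodes of the k-th core, i.e. the union of shells >= k."""
        return {n for n, s in self.shell_of.items() if s >= k}

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, k, self.thresholds[k]) for n, k in sorted(self.shell_of.items())]
        return pd.DataFrame(rows, columns=["port_id", "shell_index", "s_threshold"])


# ---------------------------------------------------------------------------
# combined degree
# ---------------------------------------------------------------------------

def _combined_degree(degree: float, weight_sum: float, params: DecompositionParams) -> float:
    if degree == 0:
        return 0.0
    # 0**0 == 1 handles beta = 0 (and alpha = 0) cleanly
    return float((degree ** params.alpha * weight_sum ** params.beta)
                 ** (1.0 / (params.alpha + params.beta)))


def weighted_out_degree(
    graph: nx.DiGraph,
    node: Hashable,
    params: DecompositionParams = DecompositionParams(),
) -> float:
    """Combined out-degree ``d' = [d^alpha (sum w)^beta]^(1/(alpha+beta))``."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    d = graph.out_degree(node)
    s = sum(w for _, _, w in graph.out_edges(node, data="weight", default=0.0))
    return _combined_degree(d, s, params)


def _all_combined_degrees(graph: nx.DiGraph, params: DecompositionParams) -> dict:
    return {n: weighted_out_degree(graph, n, params) for n in graph.nodes}


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def s_core_decompose(
    graph: nx.DiGraph,
    params: DecompositionParams = DecompositionParams(),
) -> ShellAssignment:
    """Peel the graph into s-shells at successive minimum-d' thresholds.

    Each stage removes *every* remaining node with ``d' <= s_k``
    (within :data:`PEEL_TOL`), recomputing d' on the induced subgraph
    after each sweep until the stage stabilises; the removed nodes form
    shell ``k`` and the survivors' minimum d' is the next threshold.
    One-at-a-time removal (see :func:`s_core_decompose_oracle`) yields
    the identical partition.  Empty graph -> empty assignment.
    """
    H = graph.copy()
    shell_of: dict[Hashable, int] = {}
    thresholds: list[float] = []
    k = 0
    while H.number_of_nodes() > 0:
        dprime = _all_combined_degrees(H, params)
        s_k = min(dprime.values())
        removed_any = True
        shell_nodes: list = []
        while removed_any:
            batch = [n for n, dv in dprime.items() if dv <= s_k + PEEL_TOL]
            removed_any = bool(batch)
            if removed_any:
                H.remove_nodes_from(batch)
                shell_nodes.extend(batch)
                dprime = _all_combined_degrees(H, params)
        for n in shell_nodes:
            shell_of[n] = k
        thresholds.append(s_k)
        k += 1
    return ShellAssignment(shell_of, tuple(thresholds))


def s_core_decompose_oracle(
    graph: nx.DiGraph,
    params: DecompositionParams = DecompositionParams(),
) -> ShellAssignment:
    """Reference decomposition removing one minimum-d' node at a time.

    At each step the node with the smallest current d' (ties broken by
    node id) is removed and assigned the running threshold
    ``max(threshold so far, its d')``; shells are the plateaus of that
    running threshold.  Intended for small graphs (~15 nodes); kept
    deliberately naive and independent of :func:`s_core_decompose`.
    """
    H = graph.copy()
    assigned: list[tuple[Hashable, float]] = []
    running = -np.inf
    while H.number_of_nodes() > 0:
        dprime = {n: weighted_out_degree(H, n, params) for n in H.nodes}
        m = min(dprime.values())
        victim = min(n for n, dv in dprime.items() if dv <= m + PEEL_TOL)
        running = max(running, dprime[victim])
        assigned.append((victim, running))
        H.remove_node(victim)

    shell_of: dict[Hashable, int] = {}
    thresholds: list[float] = []
    for node, thr in assigned:
        if not thresholds or thr > thresholds[-1] + PEEL_TOL:
            thresholds.append(thr)
        shell_of[node] = len(thresholds) - 1
    return ShellAssignment(shell_of, tuple(thresholds))


def k_core_decompose(graph: nx.DiGraph) -> ShellAssignment:
    """Classic unweighted k-core by out-degree, weights ignored.

    Runs the same peeling engine with ``alpha = 1, beta = 0`` so the
    combined degree reduces to the integer out-degree; shell indices are
    the ordinal rank of the distinct peeling thresholds (the thresholds
    themselves are the out-degree values at which each shell fell).
    """
    return s_core_decompose(graph, DecompositionParams(alpha=1.0, beta=0.0))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def kendall_tau(rank_a: Sequence[float], rank_b: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected) between two aligned rankings."""
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rankings must be 1-D and of equal length")
    tau = stats.kendalltau(a, b, variant="b").statistic
    return float(tau)


def core_summaries(
    graph: nx.DiGraph,
    assignment: ShellAssignment,
    params: DecompositionParams = DecompositionParams(),
) -> pd.DataFrame:
    """Per-shell and per-core statistics of a decomposition.

    One row per shell index ``k``: the shell's member count, threshold
    ``s_k`` and mean out-degree (taken in the full graph), and the same
    for the k-th *core* (union of shells >= k).  Core counts are
    non-increasing in ``k`` by nestedness.
    """
    if set(assignment.shell_of) != set(graph.nodes):
        raise ValueError("assignment does not cover exactly this graph's nodes")
    out_deg = dict(graph.out_degree())
    rows = []
    for k in range(assignment.n_shells):
        shell = assignment.shell_members(k)
        core = assignment.core_members(k)
        rows.append({
            "shell_index": k,
            "s_threshold": assignment.thresholds[k],
            "shell_size": len(shell),
            "shell_mean_out_degree": float(np.mean([out_deg[n] for n in shell])),
            "core_size": len(core),
            "core_mean_out_degree": float(np.mean([out_deg[n] for n in core])),
        })
    return pd.DataFrame(rows)
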