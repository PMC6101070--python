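"""The species invasion network (SIN).

A SIN is a directed graph ``S = (V, E, W)``: nodes are ports, an edge
``i -> j`` means shipping runs from *i* to *j*, and its weight
``w_ij = P_ij(Inv)`` is the modelled probability that this traffic causes
an invasion at *j*.  We store it as a :class:`networkx.DiGraph` with the
weight in the ``"weight"`` edge attribute and the port profile
(name, lon, lat, temperature_C, salinity_PSU) as node attributes.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .ingest import Port
from .risk import RouteRisk, port_invaded_risk

__all__ = [
    "build_sin", "write_sin", "read_sin", "top_edges", "weight_histogram",
    "invaded_risks_from_sin",
]


def build_sin(
    ports: Mapping[str, Port] | Iterable[Port],
    route_risks: Iterable[RouteRisk],
    keep_zero_weight: bool = False,
) -> nx.DiGraph:
    """Assemble the SIN from per-route risks.

    All registered ports become nodes (isolated ones included); each
    route risk becomes one directed edge with ``weight = p_inv``.
    Zero-weight routes are dropped by default — they cannot change any
    invaded risk or weighted degree — unless ``keep_zero_weight`` is set.
    Duplicate ordered pairs and self-loops are rejected.
    """
    port_list = list(ports.values()) if isinstance(ports, Mapping) else list(ports)
    G = nx.DiGraph()
    for p in port_list:
        G.add_node(p.port_id, name=p.name, lon=p.lon, lat=p.lat,
                   temperature_C=p.temperature_C, salinity_PSU=p.salinity_PSU)
    for rr in route_risks:
        if rr.source_port == rr.dest_port:
            raise ValueError(f"self-loop route {rr.source_port!r}")
        if not G.has_node(rr.source_port) or not G.has_node(rr.dest_port):
            raise KeyError(f"route {rr.source_port}->{rr.dest_port} references "
                           "an unregistered port")
        if G.has_edge(rr.source_port, rr.dest_port):
            raise ValueError(f"duplicate route {rr.source_port}->{rr.dest_port}")
        if rr.p_inv > 0.0 or keep_zero_weight:
            G.add_edge(rr.source_port, rr.dest_port, weight=rr.p_inv)
    return G


def write_sin(graph: nx.DiGraph, path, format: str = "graphml") -> None:
    """Serialize a SIN.

    ``graphml`` preserves nodes (with attributes) and edges; it is the
    full-fidelity format.  ``edgelist_csv`` writes ``source,dest,weight``
    rows only, so isolated nodes and node attributes are not represented.
    Weights are written as full-precision decimal text in both formats.
    """
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "dest", "weight"])
            for u, v, data in sorted(graph.edges(data=True)):
                w.writerow([u, v, repr(float(data["weight"]))])
    else:
        raise ValueError(f"unknown SIN format {format!r}")


def read_sin(path, format: str = "graphml") -> nx.DiGraph:
    """Read a SIN written by :func:`write_sin` (formats as documented there)."""
    if format == "graphml":
        G = nx.read_graphml(path)
        if not G.is_directed():
            raise ValueError(f"{path}: GraphML graph is not directed")
        out = nx.DiGraph()
        out.add_nodes_from(G.nodes(data=True))
        for u, v, data in G.edges(data=True):
            out.add_edge(u, v, weight=float(data["weight"]))
        return out
    if format == "edgelist_csv":
        G = nx.DiGraph()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != ["source", "dest", "weight"]:
                raise ValueError(f"{path}: expected header source,dest,weight, "
                                 f"got {reader.fieldnames}")
            for row in reader:
                try:
                    G.add_edge(row["source"], row["dest"],
                               weight=float(row["weight"]))
                except (TypeError, ValueError, KeyError) as exc:
                    raise ValueError(
                        f"{path}: malformed edge row at line {reader.line_num}"
                    ) from exc
        return G
    raise ValueError(f"unknown SIN format {format!r}")


def top_edges(graph: nx.DiGraph, n: int) -> list[tuple[str, str, float]]:
    """The ``n`` heaviest edges, weight descending, ties by (source, dest)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ranked = sorted(graph.edges(data="weight"),
                    key=lambda e: (-e[2], e[0], e[1]))
    return [(u, v, float(w)) for u, v, w in ranked[:n]]


def weight_histogram(graph: nx.DiGraph, bin_edges: Sequence[float]) -> np.ndarray:
    """Edge-weight counts over half-open bins ``[lo, hi)``, last bin closed.

    Matches :func:`numpy.histogram` binning; counts sum to the edge count
    provided the edges span all weights.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    weights = [w for _, _, w in graph.edges(data="weight")]
    counts, _ = np.histogram(weights, bins=edges)
    return counts


def invaded_risks_from_sin(graph: nx.DiGraph) -> dict[str, float]:
    """Per-port invaded risk ``P_j(Inv)`` aggregated over incoming edges."""
    return {
        node: port_invaded_risk([w for _, _, w in graph.in_edges(node, data="weight")])
        for node in graph.nodes
    }
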