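"""Shared fixtures and small generators for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from ballastnet import Port

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

T0 = datetime(2014, 1, 1, tzinfo=timezone.utc)


def hours(h: float) -> timedelta:
    return timedelta(hours=h)


def make_port(pid: str, lon: float = 0.0, lat: float = 0.0,
              temp: float = 20.0, sal: float = 35.0) -> Port:
    return Port(pid, f"Port {pid}", lon, lat, temp, sal)


def random_weighted_digraph(rng: np.random.Generator,
                            n_nodes: int | None = None,
                            max_nodes: int = 12,
                            max_edges: int = 30,
                            weight: float | None = None) -> nx.DiGraph:
    """A random digraph with isolated nodes allowed and weights in (0, 1].

    ``weight`` forces a uniform edge weight (for k-core comparisons);
    otherwise weights are drawn uniformly from (0.01, 1).
    """
    n = int(rng.integers(2, max_nodes + 1)) if n_nodes is None else n_nodes
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = int(rng.integers(0, min(max_edges, len(pairs)) + 1))
    chosen = rng.choice(len(pairs), size=m, replace=False)
    for k in chosen:
        i, j = pairs[k]
        w = weight if weight is not None else float(rng.uniform(0.01, 1.0))
        G.add_edge(i, j, weight=w)
    return G


@pytest.fixture
def simple_ports() -> dict[str, Port]:
    """Three well-separated ports: equatorial A/B and a northern C."""
    ports = [
        make_port("A", lon=0.0, lat=0.0, temp=28.0, sal=35.0),
        make_port("B", lon=30.0, lat=0.0, temp=27.0, sal=34.0),
        make_port("C", lon=10.0, lat=45.0, temp=12.0, sal=36.0),
    ]
    return {p.port_id: p for p in ports}
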