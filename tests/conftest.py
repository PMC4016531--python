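"""Shared fixtures: a small worked-example network and random-graph helpers."""

from itertools import combinations

import numpy as np
import pytest

from trimerpred.ppi_graph import (
    DomainAnnotation,
    ProteinTriplet,
    WeightedPPINetwork,
)

G0_EDGES = [
    ("A", "B", 3.0),
    ("B", "C", 5.0),
    ("A", "C", 1.0),
    ("C", "D", 2.0),
    ("A", "D", 4.0),
    ("D", "E", 6.0),
]


@pytest.fixture
def g0() -> WeightedPPINetwork:
    """Five-protein network with six weighted edges, small enough to verify
    every triplet quantity by hand."""
    net = WeightedPPINetwork()
    for u, v, w in G0_EDGES:
        net.add_edge(u, v, w)
    return net


@pytest.fixture
def g0_domains() -> DomainAnnotation:
    return DomainAnnotation({"A": ["d1", "d2"], "B": ["d1"]})


def random_network(rng: np.random.Generator, n_max: int = 12,
                   p: float = 0.35) -> WeightedPPINetwork:
    """Random weighted graph on up to ``n_max`` vertices."""
    n = int(rng.integers(3, n_max + 1))
    names = [f"P{i:02d}" for i in range(n)]
    net = WeightedPPINetwork()
    for v in names:
        net.add_vertex(v)
    for u, v in combinations(names, 2):
        if rng.random() < p:
            net.add_edge(u, v, float(rng.uniform(0.1, 10.0)))
    return net


def random_domains(rng: np.random.Generator, proteins, n_types: int = 4,
                   max_per: int = 3) -> DomainAnnotation:
    dom = DomainAnnotation()
    for p in proteins:
        k = int(rng.integers(0, max_per + 1))
        if k:
            dom.add(p, [f"d{int(i)}" for i in rng.integers(n_types, size=k)])
    return dom


def brute_force_connected_triplets(net: WeightedPPINetwork) -> set[ProteinTriplet]:
    """Cubic-scan oracle: every 3-subset whose present edges connect it."""
    out = set()
    for a, b, c in combinations(sorted(net.vertices), 3):
        n_edges = sum(
            net.has_edge(u, v) for u, v in ((a, b), (a, c), (b, c))
        )
        if n_edges >= 2:
            out.add(ProteinTriplet.of(a, b, c))
    return out
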