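"""Synthetic weighted PPI networks with planted complexes.

The generator emulates the statistical regime the predictor assumes: planted
heterotrimers are triangles with high, reliable internal weights and mostly
do not share proteins with one another; larger planted complexes are dense
cliques with equally high internal weights (their 3-subsets are the hard
negatives); background edges are sparse and weak.  Domains are assigned at
random so the domain features and the composition kernel are exercised
without necessarily carrying class signal (an optional shared per-complex
domain signature can inject some).

Weights are drawn from normal distributions truncated to stay positive.
All randomness flows from one seed through spawned child generators, so each
sub-stream (topology, weights, domains) is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .ppi_graph import (
    ComplexCatalogue,
    DomainAnnotation,
    ProteinTriplet,
    WeightedPPINetwork,
)

__all__ = ["SyntheticSpec", "generate", "benchmark_spec", "planted_heterotrimers"]

_MIN_WEIGHT = 1e-3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-complex generator.

    ``n_background_proteins`` proteins carry no planted structure; planted
    complexes bring their own members (disjoint from the background pool).
    ``internal_weight`` must dominate ``background_weight`` in mean — that
    separation is the planted signal.  ``overlap_prob`` is the probability
    that a planted heterotrimer reuses one protein of an earlier one;
    the default 0 matches the premise that heterotrimers rarely share
    proteins.  ``domain_signature_prob`` optionally gives all members of a
    planted heterotrimer an identical extra domain composition so the
    composition kernel carries signal; off by default.
    """

    n_background_proteins: int = 100
    n_heterotrimers: int = 40
    n_large_complexes: int = 10
    large_size_range: tuple[int, int] = (4, 6)
    internal_weight: tuple[float, float] = (50.0, 10.0)  # mean, sd
    background_weight: tuple[float, float] = (10.0, 5.0)
    background_edge_prob: float = 0.02
    n_domain_types: int = 30
    domains_per_protein: tuple[int, int] = (0, 4)  # inclusive range
    overlap_prob: float = 0.0
    domain_signature_prob: float = 0.0
    seed: int = 7

    def validate(self) -> None:
        if min(self.n_background_proteins, self.n_heterotrimers,
               self.n_large_complexes) < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.large_size_range
        if not (4 <= lo <= hi):
            raise ValueError(f"large complex sizes must be >= 4, got {self.large_size_range}")
        for p in (self.background_edge_prob, self.overlap_prob,
                  self.domain_signature_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.internal_weight[0] > self.background_weight[0]:
            raise ValueError(
                "internal weight mean must exceed background mean "
                f"({self.internal_weight[0]} vs {self.background_weight[0]})"
            )
        if self.n_heterotrimers > 0 or self.n_large_complexes > 0:
            if self.n_background_proteins + 3 * self.n_heterotrimers == 0 and \
               self.n_large_complexes == 0:
                raise ValueError("no proteins to generate")
        if self.domains_per_protein[0] < 0 or \
           self.domains_per_protein[0] > self.domains_per_protein[1]:
            raise ValueError(f"bad domain range {self.domains_per_protein}")
        if self.n_domain_types < 1 and self.domains_per_protein[1] > 0:
            raise ValueError("need at least one domain type")


def benchmark_spec(seed: int = 7, **overrides) -> SyntheticSpec:
    """A study-scale benchmark: 80 planted heterotrimers (positives) and
    12 size-5..7 complexes, whose connected 3-subsets number at least
    12 * C(5,3) = 120, so a 100-negative sample is always available."""
    spec = SyntheticSpec(
        n_heterotrimers=80, n_large_complexes=12, large_size_range=(5, 7),
        seed=seed,
    )
    return replace(spec, **overrides)


def _draw_weight(rng: np.random.Generator, mean: float, sd: float) -> float:
    # truncated normal: redraw a few times, then clip to stay positive
    for _ in range(10):
        w = rng.normal(mean, sd)
        if w > 0:
            return float(w)
    return _MIN_WEIGHT


def generate(
    spec: SyntheticSpec,
) -> tuple[WeightedPPINetwork, DomainAnnotation, ComplexCatalogue]:
    """Generate (network, domain annotation, complex catalogue).

    The catalogue lists every planted complex: the size-3 entries are the
    planted heterotrimers, the larger entries the negative source.
    Deterministic for a fixed spec (seed included).
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    rng_topo, rng_w, rng_dom = root.spawn(3)

    net = WeightedPPINetwork()
    cat = ComplexCatalogue()
    planted_edges: set[frozenset[str]] = set()

    def plant_clique(members: list[str]) -> None:
        for u, v in combinations(members, 2):
            w = _draw_weight(rng_w, *spec.internal_weight)
            net.add_edge(u, v, w)
            planted_edges.add(frozenset((u, v)))

    # heterotrimers: own proteins, optionally reusing one from a predecessor
    trimers: list[list[str]] = []
    for i in range(spec.n_heterotrimers):
        members = [f"T{i:03d}{c}" for c in "abc"]
        if trimers and rng_topo.random() < spec.overlap_prob:
            donor = trimers[rng_topo.integers(len(trimers))]
            members[0] = donor[rng_topo.integers(3)]
        trimers.append(members)
        plant_clique(members)
        cat.add(members)

    for i in range(spec.n_large_complexes):
        size = int(rng_topo.integers(spec.large_size_range[0],
                                     spec.large_size_range[1] + 1))
        members = [f"C{i:03d}_{j}" for j in range(size)]
        plant_clique(members)
        cat.add(members)

    background = [f"B{j:03d}" for j in range(spec.n_background_proteins)]
    for b in background:
        net.add_vertex(b)

    # sprinkle weak background edges over all proteins
    proteins = sorted(net.vertices)
    n = len(proteins)
    if n >= 2 and spec.background_edge_prob > 0:
        mask = rng_topo.random(n * (n - 1) // 2) < spec.background_edge_prob
        k = 0
        for a, b in combinations(proteins, 2):
            if mask[k] and frozenset((a, b)) not in planted_edges:
                net.add_edge(a, b, _draw_weight(rng_w, *spec.background_weight))
            k += 1

    dom = DomainAnnotation()
    lo, hi = spec.domains_per_protein
    for p in proteins:
        k = int(rng_dom.integers(lo, hi + 1))
        if k > 0:
            dom.add(p, [f"d{int(j):02d}"
                        for j in rng_dom.integers(spec.n_domain_types, size=k)])
    if spec.domain_signature_prob > 0:
        for members in trimers:
            if rng_dom.random() < spec.domain_signature_prob:
                sig_dom = f"d{int(rng_dom.integers(spec.n_domain_types)):02d}"
                for p in members:
                    dom.add(p, [sig_dom])

    return net, dom, cat


def planted_heterotrimers(cat: ComplexCatalogue) -> list[ProteinTriplet]:
    """The planted positives, as triplets."""
    return sorted(ProteinTriplet.from_iterable(c) for c in cat.of_size(3))
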