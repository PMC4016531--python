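"""Weighted PPI network, domain annotations, complex catalogue, and triplet queries.

The network is an undirected graph whose vertices are protein identifiers and
whose edges carry a strictly positive reliability weight (WI-PHI-style scores).
Candidate prediction units are *connected triplets*: sets of three distinct
proteins whose present interaction edges (two or three of the possible three)
form a single connected subgraph.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinTriplet",
    "WeightedPPINetwork",
    "DomainAnnotation",
    "ComplexCatalogue",
    "ParseError",
    "read_interaction_table",
    "write_interaction_table",
    "read_domain_table",
    "write_domain_table",
    "read_complex_catalogue",
    "write_complex_catalogue",
    "is_connected_triplet",
    "enumerate_connected_triplets",
    "triplets_containing",
    "neighboring_triplets",
]


class ParseError(ValueError):
    """Raised when an input table row cannot be parsed; names the line number."""


@dataclass(frozen=True, order=True)
class ProteinTriplet:
    """An unordered set of three distinct proteins, stored in canonical
    (lexicographically sorted) order so equality and hashing are order-free."""

    members: tuple[str, str, str]

    @staticmethod
    def of(a: str, b: str, c: str) -> "ProteinTriplet":
        if len({a, b, c}) != 3:
            raise ValueError(f"triplet members must be distinct: {(a, b, c)}")
        return ProteinTriplet(tuple(sorted((a, b, c))))

    @staticmethod
    def from_iterable(members: Iterable[str]) -> "ProteinTriplet":
        ms = list(members)
        if len(ms) != 3:
            raise ValueError(f"expected exactly 3 members, got {len(ms)}")
        return ProteinTriplet.of(*ms)

    def shares_protein(self, other: "ProteinTriplet") -> bool:
        return bool(set(self.members) & set(other.members))

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members

    def __str__(self) -> str:
        return "-".join(self.members)


class WeightedPPINetwork:
    """Undirected protein interaction graph with positive edge weights.

    No self-loops; each unordered pair is stored once. Backed by networkx.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ------------------------------------------------------

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-interaction not allowed: {u}")
        if not weight > 0:
            raise ValueError(f"edge weight must be positive: {u}-{v} = {weight}")
        self._g.add_edge(u, v, weight=float(weight))

    def add_vertex(self, v: str) -> None:
        self._g.add_node(v)

    # -- queries -----------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self._g.edges(data="weight"):
            yield u, v, d

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_vertex(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    def neighbors(self, v: str) -> set[str]:
        if v not in self._g:
            return set()
        return set(self._g[v])

    def degree(self, v: str) -> int:
        return self._g.degree(v) if v in self._g else 0


class DomainAnnotation:
    """Total map protein -> multiset of domain identifiers.

    Lookups for unannotated proteins return the empty multiset, never an error;
    a repeated domain counts as many times as it occurs.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._m: dict[str, Counter] = {}
        if mapping:
            for protein, domains in mapping.items():
                self.add(protein, domains)

    def add(self, protein: str, domains: Iterable[str]) -> None:
        self._m.setdefault(protein, Counter()).update(domains)

    def domains(self, protein: str) -> Counter:
        return self._m.get(protein, Counter())

    def count(self, protein: str) -> int:
        return sum(self._m.get(protein, Counter()).values())

    def composition(self, protein: str) -> tuple[str, ...]:
        """Sorted multiset of domains — the canonical per-protein composition."""
        return tuple(sorted(self._m.get(protein, Counter()).elements()))

    @property
    def proteins(self) -> set[str]:
        return set(self._m)


class ComplexCatalogue:
    """List of known protein complexes (unordered member sets of size >= 2)."""

    def __init__(self, complexes: Iterable[Iterable[str]] = ()) -> None:
        self._complexes: list[frozenset[str]] = []
        for members in complexes:
            self.add(members)

    def add(self, members: Iterable[str]) -> None:
        s = frozenset(members)
        if len(s) < 2:
            raise ValueError(f"complex must have >= 2 distinct members, got {sorted(s)}")
        self._complexes.append(s)

    def __len__(self) -> int:
        return len(self._complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self._complexes)

    def of_size(self, k: int) -> list[frozenset[str]]:
        return [c for c in self._complexes if len(c) == k]

    def larger_than(self, k: int) -> list[frozenset[str]]:
        return [c for c in self._complexes if len(c) > k]


# ---------------------------------------------------------------------------
# File formats (TSV-based, WI-PHI / CYC2008 flat-export style)
# ---------------------------------------------------------------------------


def _split_row(line: str, sep: str | None) -> list[str]:
    return line.split(sep) if sep else line.split()


def read_interaction_table(
    path: str | Path,
    sep: str | None = None,
    columns: tuple[int, int, int] = (0, 1, 2),
) -> WeightedPPINetwork:
    """Read a 3-column interaction table (proteinA, proteinB, weight).

    ``sep=None`` splits on any whitespace (tabs included). ``columns`` selects
    the (proteinA, proteinB, weight) column indices for non-standard layouts.
    A header row is auto-detected (first row whose weight field is not numeric).
    Self-interactions are dropped; duplicate pairs keep the maximum weight.
    """
    net = WeightedPPINetwork()
    ia, ib, iw = columns
    need = max(columns) + 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line, sep)
            if len(fields) < need:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {need} columns, got {len(fields)}"
                )
            a, b = fields[ia], fields[ib]
            try:
                w = float(fields[iw])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: weight {fields[iw]!r} is not a number"
                ) from None
            if not w > 0:
                raise ParseError(f"{path}: line {lineno}: non-positive weight {w}")
            if a == b:
                logger.debug("dropping self-interaction %s at line %d", a, lineno)
                continue
            if net.has_edge(a, b):
                old = net.weight(a, b)
                if w != old:
                    logger.warning(
                        "duplicate pair %s-%s (weights %g, %g): keeping maximum",
                        a, b, old, w,
                    )
                w = max(w, old)
            net.add_edge(a, b, w)
    return net


def write_interaction_table(net: WeightedPPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w:g}\n")


def read_domain_table(path: str | Path) -> DomainAnnotation:
    """Read a table whose first column is a protein ID and remaining columns
    are domain IDs; repeated rows for one protein merge their multisets."""
    dom = DomainAnnotation()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            dom.add(fields[0], fields[1:])
    return dom


def write_domain_table(dom: DomainAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(dom.proteins):
            fh.write("\t".join([protein, *dom.composition(protein)]) + "\n")


def read_complex_catalogue(path: str | Path) -> ComplexCatalogue:
    """Read one complex per line, member IDs whitespace/tab separated."""
    cat = ComplexCatalogue()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members = set(line.split())
            if len(members) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: complex needs >= 2 distinct members"
                )
            cat.add(members)
    return cat


def write_complex_catalogue(cat: ComplexCatalogue, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cx in cat:
            fh.write("\t".join(sorted(cx)) + "\n")


# ---------------------------------------------------------------------------
# Triplet enumeration
# ---------------------------------------------------------------------------


def is_connected_triplet(net: WeightedPPINetwork, t: ProteinTriplet) -> bool:
    """True iff the edges present among the three members form a connected
    subgraph: with three vertices that means >= 2 of the 3 possible edges
    (any two edges on three vertices necessarily share a vertex)."""
    a, b, c = t.members
    n_present = sum(
        1 for u, v in ((a, b), (a, c), (b, c)) if net.has_edge(u, v)
    )
    return n_present >= 2


def enumerate_connected_triplets(net: WeightedPPINetwork) -> list[ProteinTriplet]:
    """All connected triplets, each exactly once, in deterministic sorted order.

    Enumerates locally from edges: each edge (i, j) is extended by the
    neighbours of i or j, so cost scales with edges times degree rather than
    with all vertex 3-subsets.
    """
    seen: set[ProteinTriplet] = set()
    for u, v, _ in net.edges():
        for r in (net.neighbors(u) | net.neighbors(v)) - {u, v}:
            seen.add(ProteinTriplet.of(u, v, r))
    return sorted(seen)


def triplets_containing(net: WeightedPPINetwork, p: str) -> set[ProteinTriplet]:
    """All connected triplets with ``p`` as a member.

    A connected triplet {p, a, b} has either both edges at p (p-a, p-b), or a
    path through a neighbour (p-a, a-b); both cases are covered below.
    """
    out: set[ProteinTriplet] = set()
    nbrs = net.neighbors(p)
    for a, b in combinations(sorted(nbrs), 2):
        out.add(ProteinTriplet.of(p, a, b))
    for a in nbrs:
        for b in net.neighbors(a) - {p}:
            out.add(ProteinTriplet.of(p, a, b))
    return out


def _max_internal_weight(net: WeightedPPINetwork, t: ProteinTriplet) -> float:
    ws = [
        net.weight(u, v)
        for u, v in combinations(t.members, 2)
        if net.has_edge(u, v)
    ]
    return max(ws) if ws else 0.0


def neighboring_triplets(
    net: WeightedPPINetwork,
    x: ProteinTriplet,
    cap: int | None = None,
) -> set[ProteinTriplet]:
    """N(x): every connected triplet sharing >= 1 protein with x, excluding x.

    Computed over the whole network (labels play no role). ``cap``, if given,
    bounds the set size on hub proteins by keeping the triplets with the
    largest maximum internal weight; default is unlimited.
    """
    out: set[ProteinTriplet] = set()
    for p in x.members:
        out |= triplets_containing(net, p)
    out.discard(x)
    if cap is not None and len(out) > cap:
        ranked = sorted(out, key=lambda t: (-_max_internal_weight(net, t), t))
        out = set(ranked[:cap])
    return out
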