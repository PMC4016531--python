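"""Graph-derived feature vector for a candidate triplet.

Seven features summarise how tightly the three proteins interact with one
another (F1, F2), how strongly they interact with the rest of the network
(F3, F4), whether some outside protein binds two of them at once and so hints
at a larger complex (F5), and how domain-rich the members are (F6, F7).
A true heterotrimer is expected to have high internal weights, low boundary
weights, and no strong doubly-attached outsider.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ppi_graph import (
    DomainAnnotation,
    ProteinTriplet,
    WeightedPPINetwork,
    is_connected_triplet,
)

__all__ = ["Phase1Vector", "phase1_features"]

N_PHASE1_FEATURES = 7


@dataclass(frozen=True)
class Phase1Vector:
    """The 7 graph/domain features of a triplet.

    f1/f2: max/min weight over the internal edges actually present.
    f3/f4: max/min weight over edges from a member to an external neighbour.
    f5: max over external r of the second-largest weight linking r to the
        triplet, i.e. max over member pairs p != q of min(w_pr, w_qr).
    f6/f7: max/min per-member domain count (multiset cardinality).
    Empty ranges (no external neighbours, no domains) yield 0.
    """

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f1, self.f2, self.f3, self.f4, self.f5, self.f6, self.f7],
            dtype=float,
        )


def phase1_features(
    net: WeightedPPINetwork,
    dom: DomainAnnotation,
    x: ProteinTriplet,
) -> Phase1Vector:
    """Compute the 7 features for a connected triplet.

    Raises ValueError if ``x`` is not connected in ``net`` (fewer than two of
    its three possible edges present).
    """
    if not is_connected_triplet(net, x):
        raise ValueError(f"triplet {x} is not connected in the network")

    members = x.members
    internal = [
        net.weight(u, v) for u, v in combinations(members, 2) if net.has_edge(u, v)
    ]
    f1, f2 = max(internal), min(internal)

    # weights from each external neighbour r to the members it touches
    external: dict[str, list[float]] = {}
    for p in members:
        for r in net.neighbors(p):
            if r not in x:
                external.setdefault(r, []).append(net.weight(p, r))

    if external:
        all_ext = [w for ws in external.values() for w in ws]
        f3, f4 = max(all_ext), min(all_ext)
    else:
        f3 = f4 = 0.0

    # F5: best min(w_pr, w_qr) over member pairs = second-largest weight of r
    f5 = 0.0
    for ws in external.values():
        if len(ws) >= 2:
            f5 = max(f5, sorted(ws)[-2])

    counts = [dom.count(p) for p in members]
    return Phase1Vector(f1, f2, f3, f4, f5, float(max(counts)), float(min(counts)))
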