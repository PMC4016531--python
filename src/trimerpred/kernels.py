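"""Domain composition kernel and the combined Gram matrix.

Two triplets are equivalent under the domain composition relation when some
permutation matches their proteins so that matched proteins carry identical
domain multisets.  The kernel K_c is the 0/1 indicator of that equivalence;
the classifiers operate on Gram matrices of the form

    G[i, j] = <f(x_i), f(x_j)> + alpha * K_c(x_i, x_j)

with a nonnegative mixing constant alpha.  Sorting each protein's domain
multiset, then sorting the three per-protein compositions, yields a canonical
signature whose equality realises the exists-a-permutation test without
iterating over the symmetric group.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .ppi_graph import DomainAnnotation, ProteinTriplet

__all__ = [
    "TripletDomainSignature",
    "triplet_signature",
    "domain_composition_kernel",
    "combined_gram",
]

#: canonical form: sorted 3-tuple of per-protein compositions, each itself a
#: sorted tuple of domain IDs (multiset, repeats preserved)
TripletDomainSignature = tuple[tuple[str, ...], ...]


def triplet_signature(dom: DomainAnnotation, x: ProteinTriplet) -> TripletDomainSignature:
    """Canonical domain signature of a triplet; equal signatures iff the
    triplets are equivalent under the permutation-matching relation."""
    return tuple(sorted(dom.composition(p) for p in x.members))


def domain_composition_kernel(
    si: TripletDomainSignature, sj: TripletDomainSignature
) -> float:
    """K_c: 1.0 if the two signatures are equal, else 0.0."""
    return 1.0 if si == sj else 0.0


def combined_gram(
    feature_vectors: Sequence[np.ndarray] | np.ndarray,
    signatures: Sequence[TripletDomainSignature],
    alpha: float,
    feature_vectors_cols: Sequence[np.ndarray] | np.ndarray | None = None,
    signatures_cols: Sequence[TripletDomainSignature] | None = None,
) -> np.ndarray:
    """Gram matrix <f_i, f_j> + alpha * K_c(s_i, s_j).

    With only the first pair of arguments this is the square symmetric Gram
    over one list; passing the ``_cols`` arguments builds the rectangular
    cross-Gram (rows = first list, e.g. test; cols = second list, e.g. train)
    used at prediction time.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    F = np.asarray(feature_vectors, dtype=float)
    if len(F) != len(signatures):
        raise ValueError(
            f"feature/signature length mismatch: {len(F)} vs {len(signatures)}"
        )
    if feature_vectors_cols is None:
        Fc, sc = F, signatures
    else:
        Fc = np.asarray(feature_vectors_cols, dtype=float)
        sc = signatures_cols
        if sc is None or len(Fc) != len(sc):
            raise ValueError("column features require matching column signatures")

    gram = F @ Fc.T
    if alpha > 0:
        # map signatures to integer class ids so K_c is a broadcast equality
        ids: dict[TripletDomainSignature, int] = {}
        ri = np.array([ids.setdefault(s, len(ids)) for s in signatures])
        ci = np.array([ids.setdefault(s, len(ids)) for s in sc])
        gram = gram + alpha * (ri[:, None] == ci[None, :])
    return gram
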