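"""Two-phase learning for heterotrimer prediction.

Phase 1 fits a max-margin classifier on the 7 graph/domain features over the
precomputed Gram <f1, f1'> + alpha*K_c and exposes its discriminant value
y(x).  The guiding assumption is that true heterotrimers rarely share a
protein with one another, so a candidate's neighbourhood N(x) — every
connected triplet sharing a protein with x — should not score high together
with x.  Phase 2 therefore summarises the phase-1 discriminants over N(x)
into four extra features (own value; mean of the positive neighbour values;
mean of the negative ones; mean of all — positives and negatives averaged
separately so outliers do not cancel), concatenates them with f1 into an
11-dimensional vector, and fits a second classifier (max-margin or sparse
Bayesian) on the analogous Gram.

Only training data enter parameter estimation; neighbour triplets need no
labels, they are only scored by the phase-1 discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVC

from .features import phase1_features
from .kernels import TripletDomainSignature, combined_gram, triplet_signature
from .ppi_graph import (
    DomainAnnotation,
    ProteinTriplet,
    WeightedPPINetwork,
    is_connected_triplet,
    neighboring_triplets,
)
from .rvm import RVMModel, design_matrix, fit_rvm

__all__ = [
    "LabeledTriplet",
    "TrainedKernelModel",
    "Phase2Vector",
    "TwoPhaseConfig",
    "TwoPhaseModel",
    "train_phase1",
    "phase2_features",
    "assemble_phase2",
    "fit_two_phase",
    "predict_two_phase",
    "FeatureCache",
]

SecondClassifier = Literal["max-margin", "sparse-bayes"]


@dataclass(frozen=True)
class LabeledTriplet:
    triplet: ProteinTriplet
    label: int  # +1 heterotrimer, -1 otherwise

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +-1, got {self.label}")


@dataclass
class TrainedKernelModel:
    """Kernel discriminant y(x) = sum_i a_i K(x_i, x) + b.

    ``coef`` has one entry per training example; only support vectors are
    nonzero.  Callers classify by the sign of the discriminant (0 -> -1).
    """

    coef: np.ndarray
    bias: float

    @property
    def n_train(self) -> int:
        return len(self.coef)

    def discriminant(self, kernel_rows: np.ndarray) -> np.ndarray:
        kernel_rows = np.atleast_2d(np.asarray(kernel_rows, dtype=float))
        if kernel_rows.shape[1] != self.n_train:
            raise ValueError(
                f"kernel row length {kernel_rows.shape[1]} != "
                f"{self.n_train} training examples"
            )
        return kernel_rows @ self.coef + self.bias


def train_phase1(
    gram: np.ndarray, labels: Sequence[int], cost: float = 1.0
) -> TrainedKernelModel:
    """Soft-margin max-margin fit on a precomputed Gram matrix."""
    gram = np.asarray(gram, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    svc = SVC(C=cost, kernel="precomputed")
    svc.fit(gram, y)
    coef = np.zeros(gram.shape[0])
    coef[svc.support_] = svc.dual_coef_[0]
    return TrainedKernelModel(coef=coef, bias=float(svc.intercept_[0]))


@dataclass(frozen=True)
class Phase2Vector:
    """Discriminant-derived features of a triplet.

    f2s: own discriminant; f2p/f2n: mean of the strictly positive / strictly
    negative neighbour discriminants (0 when none); f2a: mean over all of
    N(x) (0 when N(x) is empty).  By construction f2n <= f2a <= f2p.
    """

    f2s: float
    f2p: float
    f2n: float
    f2a: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f2s, self.f2p, self.f2n, self.f2a], dtype=float)


def phase2_features(y_own: float, y_neighbors: Sequence[float]) -> Phase2Vector:
    ys = np.asarray(y_neighbors, dtype=float)
    pos = ys[ys > 0]
    neg = ys[ys < 0]
    return Phase2Vector(
        f2s=float(y_own),
        f2p=float(pos.mean()) if pos.size else 0.0,
        f2n=float(neg.mean()) if neg.size else 0.0,
        f2a=float(ys.mean()) if ys.size else 0.0,
    )


def assemble_phase2(f1: np.ndarray, f2: Phase2Vector) -> np.ndarray:
    """The 11-dimensional phase-2 vector (F1..F7, f2s, f2p, f2n, f2a)."""
    return np.concatenate([np.asarray(f1, dtype=float), f2.as_array()])


@dataclass(frozen=True)
class TwoPhaseConfig:
    alpha: float = 0.5
    cost: float = 1.0
    second_classifier: SecondClassifier = "max-margin"
    neighbor_cap: int | None = None


class FeatureCache:
    """Memoises per-triplet features, signatures and neighbour sets for one
    (network, annotation) pair; shared across folds in cross-validation since
    neighbour sets overlap heavily."""

    def __init__(self, net: WeightedPPINetwork, dom: DomainAnnotation,
                 neighbor_cap: int | None = None) -> None:
        self.net = net
        self.dom = dom
        self.neighbor_cap = neighbor_cap
        self._f1: dict[ProteinTriplet, np.ndarray] = {}
        self._sig: dict[ProteinTriplet, TripletDomainSignature] = {}
        self._nbrs: dict[ProteinTriplet, list[ProteinTriplet]] = {}

    def f1(self, t: ProteinTriplet) -> np.ndarray:
        out = self._f1.get(t)
        if out is None:
            out = self._f1[t] = phase1_features(self.net, self.dom, t).as_array()
        return out

    def signature(self, t: ProteinTriplet) -> TripletDomainSignature:
        out = self._sig.get(t)
        if out is None:
            out = self._sig[t] = triplet_signature(self.dom, t)
        return out

    def neighbors(self, t: ProteinTriplet) -> list[ProteinTriplet]:
        out = self._nbrs.get(t)
        if out is None:
            out = self._nbrs[t] = sorted(
                neighboring_triplets(self.net, t, cap=self.neighbor_cap)
            )
        return out

    def f1_matrix(self, triplets: Sequence[ProteinTriplet]) -> np.ndarray:
        if not triplets:
            return np.zeros((0, 7))
        return np.vstack([self.f1(t) for t in triplets])

    def signatures(self, triplets: Sequence[ProteinTriplet]) -> list[TripletDomainSignature]:
        return [self.signature(t) for t in triplets]


@dataclass
class TwoPhaseModel:
    """Fitted phase-1 + phase-2 pair with everything needed for prediction."""

    config: TwoPhaseConfig
    train_triplets: list[ProteinTriplet]
    phase1: TrainedKernelModel
    phase2: TrainedKernelModel | RVMModel
    train_f1: np.ndarray  # (n_train, 7)
    train_f2: np.ndarray  # (n_train, 11)
    train_signatures: list[TripletDomainSignature]
    cache: FeatureCache = field(repr=False)

    def phase1_discriminants(self, triplets: Sequence[ProteinTriplet]) -> np.ndarray:
        """y(x) for arbitrary connected triplets via cross-Gram rows against
        the training set."""
        if not triplets:
            return np.zeros(0)
        rows = combined_gram(
            self.cache.f1_matrix(triplets),
            self.cache.signatures(triplets),
            self.config.alpha,
            self.train_f1,
            self.train_signatures,
        )
        return self.phase1.discriminant(rows)

    def phase2_vector(self, x: ProteinTriplet) -> np.ndarray:
        y_own = float(self.phase1_discriminants([x])[0])
        y_nbrs = self.phase1_discriminants(self.cache.neighbors(x))
        return assemble_phase2(self.cache.f1(x), phase2_features(y_own, y_nbrs))


def _fit_second(
    gram2: np.ndarray, labels: np.ndarray, config: TwoPhaseConfig
) -> TrainedKernelModel | RVMModel:
    if config.second_classifier == "max-margin":
        return train_phase1(gram2, labels, cost=config.cost)
    if config.second_classifier == "sparse-bayes":
        return fit_rvm(design_matrix(gram2), labels)
    raise ValueError(f"unknown second classifier {config.second_classifier!r}")


def fit_two_phase(
    train: Sequence[LabeledTriplet],
    net: WeightedPPINetwork,
    dom: DomainAnnotation,
    config: TwoPhaseConfig = TwoPhaseConfig(),
    cache: FeatureCache | None = None,
) -> TwoPhaseModel:
    """Fit both phases on labelled training triplets.

    Phase-1 discriminants for the training triplets are taken in-sample from
    the phase-1 model fitted on the full training set; neighbour triplets are
    scored through cross-kernel rows and never need labels.
    """
    if not train:
        raise ValueError("training set is empty")
    if cache is None:
        cache = FeatureCache(net, dom, neighbor_cap=config.neighbor_cap)
    triplets = [ex.triplet for ex in train]
    labels = np.array([ex.label for ex in train])

    F1 = cache.f1_matrix(triplets)
    sigs = cache.signatures(triplets)
    gram1 = combined_gram(F1, sigs, config.alpha)
    phase1 = train_phase1(gram1, labels, cost=config.cost)

    # score every training triplet and all members of its neighbourhood
    y_train = phase1.discriminant(gram1)
    nbr_lists = [cache.neighbors(t) for t in triplets]
    unique_nbrs = sorted({t for lst in nbr_lists for t in lst})
    if unique_nbrs:
        rows = combined_gram(
            cache.f1_matrix(unique_nbrs),
            cache.signatures(unique_nbrs),
            config.alpha,
            F1,
            sigs,
        )
        y_by_triplet = dict(zip(unique_nbrs, phase1.discriminant(rows)))
    else:
        y_by_triplet = {}

    F2 = np.vstack([
        assemble_phase2(
            F1[i],
            phase2_features(y_train[i], [y_by_triplet[t] for t in nbr_lists[i]]),
        )
        for i in range(len(triplets))
    ])
    gram2 = combined_gram(F2, sigs, config.alpha)
    phase2 = _fit_second(gram2, labels, config)

    return TwoPhaseModel(
        config=config,
        train_triplets=list(triplets),
        phase1=phase1,
        phase2=phase2,
        train_f1=F1,
        train_f2=F2,
        train_signatures=sigs,
        cache=cache,
    )


def _phase2_scores(model: TwoPhaseModel, F2_test: np.ndarray,
                   sigs_test: list[TripletDomainSignature]) -> np.ndarray:
    rows = combined_gram(
        F2_test, sigs_test, model.config.alpha,
        model.train_f2, model.train_signatures,
    )
    if isinstance(model.phase2, RVMModel):
        return model.phase2.decision(design_matrix(rows))
    return model.phase2.discriminant(rows)


def predict_two_phase(
    model: TwoPhaseModel,
    x: ProteinTriplet,
    net: WeightedPPINetwork | None = None,
    dom: DomainAnnotation | None = None,
) -> tuple[int, float]:
    """Predict one triplet: (+-1 label, phase-2 discriminant score).

    A score of exactly 0 is classified negative.  ``net``/``dom`` default to
    the ones the model was fitted on.
    """
    cache = model.cache
    if net is not None and net is not cache.net:
        raise ValueError("model was fitted on a different network")
    if not is_connected_triplet(cache.net, x):
        raise ValueError(f"triplet {x} is not connected in the network")
    f2 = model.phase2_vector(x)
    score = float(
        _phase2_scores(model, f2[None, :], [cache.signature(x)])[0]
    )
    return (1 if score > 0 else -1), score


def predict_two_phase_many(
    model: TwoPhaseModel, xs: Sequence[ProteinTriplet]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised prediction: (labels, scores) for a list of triplets."""
    if not xs:
        return np.zeros(0, dtype=int), np.zeros(0)
    F2 = np.vstack([model.phase2_vector(x) for x in xs])
    scores = _phase2_scores(model, F2, model.cache.signatures(xs))
    return np.where(scores > 0, 1, -1), scores
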