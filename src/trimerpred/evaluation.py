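"""Dataset construction and repeated stratified cross-validation.

Positives are the size-3 complexes of the catalogue that are connected in
the interaction network; negatives are sampled uniformly without replacement
from the connected 3-subsets of larger complexes (excluding any that
coincide with a catalogue heterotrimer).  Negatives drawn from inside larger
complexes are deliberately hard: their internal edges are as reliable as a
true trimer's, so the boundary features and the neighbourhood discriminants
carry the signal.

Performance is summarised by accuracy, precision, recall and F-measure
(harmonic mean of precision and recall); zero-denominator cases are defined
as 0 so an all-negative fold yields F = 0 rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .kernels import combined_gram
from .ppi_graph import (
    ComplexCatalogue,
    DomainAnnotation,
    ProteinTriplet,
    WeightedPPINetwork,
    is_connected_triplet,
)
from .twophase import (
    FeatureCache,
    LabeledTriplet,
    TwoPhaseConfig,
    fit_two_phase,
    predict_two_phase_many,
    train_phase1,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "metrics",
    "build_dataset",
    "negative_pool",
    "cross_validate",
    "METHODS",
]

Method = Literal["two-phase-mm", "two-phase-sb", "single-phase"]
METHODS: tuple[Method, ...] = ("two-phase-mm", "two-phase-sb", "single-phase")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @staticmethod
    def from_predictions(
        true: Sequence[int], predicted: Sequence[int]
    ) -> "ConfusionCounts":
        t = np.asarray(true)
        p = np.asarray(predicted)
        return ConfusionCounts(
            tp=int(np.sum((t == 1) & (p == 1))),
            fp=int(np.sum((t == -1) & (p == 1))),
            tn=int(np.sum((t == -1) & (p == -1))),
            fn=int(np.sum((t == 1) & (p == -1))),
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F-measure from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated examples")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricSet(accuracy, precision, recall, f)


def _mean_metrics(ms: Sequence[MetricSet]) -> MetricSet:
    return MetricSet(
        float(np.mean([m.accuracy for m in ms])),
        float(np.mean([m.precision for m in ms])),
        float(np.mean([m.recall for m in ms])),
        float(np.mean([m.f_measure for m in ms])),
    )


def connected_positives(
    catalogue: ComplexCatalogue, net: WeightedPPINetwork
) -> list[ProteinTriplet]:
    """Catalogue heterotrimers connected in the network, sorted; trimers with
    a disconnected member are eliminated."""
    out = []
    for cx in catalogue.of_size(3):
        t = ProteinTriplet.from_iterable(cx)
        if is_connected_triplet(net, t):
            out.append(t)
    return sorted(set(out))


def negative_pool(
    catalogue: ComplexCatalogue, net: WeightedPPINetwork
) -> list[ProteinTriplet]:
    """Connected 3-subsets of complexes of size > 3 that are not catalogue
    heterotrimers, deduplicated and sorted."""
    trimers = {frozenset(c) for c in catalogue.of_size(3)}
    pool: set[ProteinTriplet] = set()
    for cx in catalogue.larger_than(3):
        for sub in combinations(sorted(cx), 3):
            if frozenset(sub) in trimers:
                continue
            t = ProteinTriplet.of(*sub)
            if is_connected_triplet(net, t):
                pool.add(t)
    return sorted(pool)


def build_dataset(
    catalogue: ComplexCatalogue,
    net: WeightedPPINetwork,
    n_negatives: int = 100,
    seed: int = 0,
) -> list[LabeledTriplet]:
    """Labelled examples: all connected heterotrimers as positives plus a
    uniform random sample (without replacement) of ``n_negatives`` from the
    negative pool."""
    positives = connected_positives(catalogue, net)
    pool = negative_pool(catalogue, net)
    if n_negatives > len(pool):
        raise ValueError(
            f"requested {n_negatives} negatives but the eligible pool has "
            f"only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_negatives, replace=False)
    negatives = [pool[i] for i in sorted(idx)]
    return [LabeledTriplet(t, 1) for t in positives] + [
        LabeledTriplet(t, -1) for t in negatives
    ]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _fit_predict(
    method: Method,
    train: list[LabeledTriplet],
    test: list[LabeledTriplet],
    cache: FeatureCache,
    alpha: float,
    cost: float,
) -> np.ndarray:
    """Train on one fold complement, return +-1 predictions on the fold."""
    test_triplets = [ex.triplet for ex in test]
    if method == "single-phase":
        triplets = [ex.triplet for ex in train]
        labels = np.array([ex.label for ex in train])
        F1 = cache.f1_matrix(triplets)
        sigs = cache.signatures(triplets)
        model = train_phase1(combined_gram(F1, sigs, alpha), labels, cost=cost)
        rows = combined_gram(
            cache.f1_matrix(test_triplets),
            cache.signatures(test_triplets),
            alpha, F1, sigs,
        )
        scores = model.discriminant(rows)
        return np.where(scores > 0, 1, -1)
    config = TwoPhaseConfig(
        alpha=alpha,
        cost=cost,
        second_classifier="sparse-bayes" if method == "two-phase-sb" else "max-margin",
    )
    model = fit_two_phase(train, cache.net, cache.dom, config, cache=cache)
    labels_pred, _ = predict_two_phase_many(model, test_triplets)
    return labels_pred


def cross_validate(
    catalogue: ComplexCatalogue,
    net: WeightedPPINetwork,
    dom: DomainAnnotation,
    methods: Sequence[Method] = ("two-phase-mm",),
    folds: int = 10,
    repeats: int = 10,
    n_negatives: int = 100,
    alpha: float = 0.5,
    cost: float = 1.0,
    seed: int = 0,
    pooling: Literal["per-fold", "pooled"] = "per-fold",
    dataset: Sequence[LabeledTriplet] | None = None,
) -> dict[Method, MetricSet]:
    """Repeated stratified k-fold cross-validation.

    Each repeat draws a fresh negative sample (positives are kept), splits
    the dataset into stratified folds, trains on k-1 folds and evaluates on
    the held-out fold.  With ``pooling='per-fold'`` metrics are computed per
    fold from that fold's confusion counts and averaged over folds, then over
    repeats; ``'pooled'`` pools counts over all folds of a repeat first.
    All randomness derives from ``seed``.  A prebuilt ``dataset`` bypasses
    negative resampling (useful with ``repeats=1``).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    results: dict[Method, list[MetricSet]] = {m: [] for m in methods}
    cache = FeatureCache(net, dom)
    for rep in range(repeats):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        data = (
            list(dataset)
            if dataset is not None
            else build_dataset(catalogue, net, n_negatives, seed=rep_seed)
        )
        y = np.array([ex.label for ex in data])
        if len(np.unique(y)) < 2:
            raise ValueError("dataset must contain both classes")
        if np.sum(y == 1) < folds:
            logger.warning(
                "only %d positives for %d folds; stratification keeps every "
                "fold from being positive-free where possible",
                int(np.sum(y == 1)), folds,
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_counts: dict[Method, list[ConfusionCounts]] = {m: [] for m in methods}
        for train_idx, test_idx in skf.split(np.zeros(len(data)), y):
            train = [data[i] for i in train_idx]
            test = [data[i] for i in test_idx]
            for method in methods:
                pred = _fit_predict(method, train, test, cache, alpha, cost)
                fold_counts[method].append(
                    ConfusionCounts.from_predictions(y[test_idx], pred)
                )
        for method in methods:
            if pooling == "pooled":
                total = sum(fold_counts[method], ConfusionCounts())
                results[method].append(metrics(total))
            else:
                results[method].append(
                    _mean_metrics([metrics(c) for c in fold_counts[method]])
                )
    return {m: _mean_metrics(results[m]) for m in methods}
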