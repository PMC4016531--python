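"""Phase-1 training, discriminants, phase-2 features, and the fitted pair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimerpred.kernels import combined_gram
from trimerpred.ppi_graph import ProteinTriplet, enumerate_connected_triplets
from trimerpred.synthetic import SyntheticSpec, generate, planted_heterotrimers
from trimerpred.twophase import (
    LabeledTriplet,
    TrainedKernelModel,
    TwoPhaseConfig,
    assemble_phase2,
    fit_two_phase,
    phase2_features,
    predict_two_phase,
    predict_two_phase_many,
    train_phase1,
)


class TestTrainPhase1:
    def test_separable_pair(self):
        gram = np.eye(2) + 1.0
        model = train_phase1(gram, [1, -1])
        pred = np.sign(model.discriminant(gram))
        assert pred.tolist() == [1, -1]

    def test_separable_set_training_accuracy(self):
        rng = np.random.default_rng(0)
        F = np.vstack([rng.normal(5, 0.5, (10, 3)), rng.normal(-5, 0.5, (10, 3))])
        labels = np.array([1] * 10 + [-1] * 10)
        gram = F @ F.T
        model = train_phase1(gram, labels, cost=1.0)
        assert np.all(np.sign(model.discriminant(gram)) == labels)

    def test_discriminant_matches_reference_solver(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(1)
        F = rng.normal(size=(20, 4))
        labels = np.where(F[:, 0] + 0.3 * rng.normal(size=20) > 0, 1, -1)
        if len(np.unique(labels)) < 2:
            labels[0] = -labels[0]
        gram = F @ F.T
        model = train_phase1(gram, labels, cost=1.0)
        ref = SVC(C=1.0, kernel="precomputed").fit(gram, labels)
        np.testing.assert_allclose(
            model.discriminant(gram), ref.decision_function(gram), atol=1e-10
        )

    def test_contradictory_duplicates_tolerated(self):
        gram = np.ones((2, 2))
        model = train_phase1(gram, [1, -1])
        pred = np.where(model.discriminant(gram) > 0, 1, -1)
        assert (pred == [1, -1]).sum() == 1  # exactly one of the two is wrong

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_phase1(np.eye(3), [1, 1, 1])


class TestDiscriminant:
    def test_zero_coefficients_return_bias(self):
        m = TrainedKernelModel(coef=np.zeros(4), bias=0.7)
        assert m.discriminant(np.ones((1, 4)))[0] == 0.7

    def test_linearity_in_coefficients(self):
        row = np.array([[1.0, 2.0, 0.0]])
        m1 = TrainedKernelModel(coef=np.array([0.0, 0.5, 0.0]), bias=0.1)
        m2 = TrainedKernelModel(coef=np.array([0.0, 1.0, 0.0]), bias=0.1)
        assert m2.discriminant(row)[0] - 0.1 == pytest.approx(
            2 * (m1.discriminant(row)[0] - 0.1)
        )

    def test_row_length_mismatch_rejected(self):
        m = TrainedKernelModel(coef=np.zeros(4), bias=0.0)
        with pytest.raises(ValueError):
            m.discriminant(np.ones((1, 3)))


class TestPhase2Features:
    def test_empty_neighborhood_zero_conventions(self):
        f2 = phase2_features(1.2, [])
        assert (f2.f2s, f2.f2p, f2.f2n, f2.f2a) == (1.2, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        f2 = phase2_features(0.0, [1.0, 3.0, -2.0])
        assert f2.f2p == pytest.approx(2.0)
        assert f2.f2n == pytest.approx(-2.0)
        assert f2.f2a == pytest.approx(2 / 3)

    def test_zeros_are_neither_positive_nor_negative(self):
        f2 = phase2_features(0.5, [0.0, 0.0])
        assert (f2.f2p, f2.f2n, f2.f2a) == (0.0, 0.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        y_own=st.floats(-10, 10),
        nbrs=st.lists(st.floats(-10, 10), max_size=20),
    )
    def test_ordering_invariant(self, y_own, nbrs):
        f2 = phase2_features(y_own, nbrs)
        assert f2.f2p >= 0
        assert f2.f2n <= 0
        if nbrs:
            assert f2.f2n <= f2.f2a + 1e-12
            assert f2.f2a <= f2.f2p + 1e-12


class TestAssemble:
    def test_concatenation_order(self):
        f1 = np.array([5, 1, 4, 2, 2, 2, 0], dtype=float)
        f2 = phase2_features(1.2, [])
        v = assemble_phase2(f1, f2)
        assert v.tolist() == [5, 1, 4, 2, 2, 2, 0, 1.2, 0, 0, 0]

    def test_zero_vectors(self):
        v = assemble_phase2(np.zeros(7), phase2_features(0.0, []))
        assert v.tolist() == [0.0] * 11


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(n_background_proteins=60, n_heterotrimers=15,
                         n_large_complexes=5, seed=5)
    net, dom, cat = generate(spec)
    positives = planted_heterotrimers(cat)
    from trimerpred.evaluation import negative_pool

    negatives = negative_pool(cat, net)[:20]
    data = [LabeledTriplet(t, 1) for t in positives] + [
        LabeledTriplet(t, -1) for t in negatives
    ]
    return net, dom, data


class TestFitPredict:
    def test_phase2_not_worse_in_sample(self, planted):
        net, dom, data = planted
        model = fit_two_phase(data, net, dom, TwoPhaseConfig(alpha=0.5))
        labels = np.array([ex.label for ex in data])
        # phase-1 in-sample accuracy
        g1 = combined_gram(model.train_f1, model.train_signatures, 0.5)
        acc1 = np.mean(np.where(model.phase1.discriminant(g1) > 0, 1, -1) == labels)
        pred2, _ = predict_two_phase_many(model, [ex.triplet for ex in data])
        acc2 = np.mean(pred2 == labels)
        assert acc2 >= acc1

    def test_training_positive_recovered(self, planted):
        net, dom, data = planted
        model = fit_two_phase(data, net, dom)
        pos = next(ex.triplet for ex in data if ex.label == 1)
        label, score = predict_two_phase(model, pos)
        assert label == 1 and score > 0

    def test_deterministic_predictions(self, planted):
        net, dom, data = planted
        xs = [ex.triplet for ex in data]
        m1 = fit_two_phase(data, net, dom)
        m2 = fit_two_phase(data, net, dom)
        _, s1 = predict_two_phase_many(m1, xs)
        _, s2 = predict_two_phase_many(m2, xs)
        np.testing.assert_array_equal(s1, s2)

    def test_isolated_triangles_degenerate_neighborhoods(self):
        # no triplet has any neighbour: phase-2 reduces to (f1, y, 0, 0, 0)
        spec = SyntheticSpec(n_background_proteins=0, n_heterotrimers=6,
                             n_large_complexes=2, background_edge_prob=0.0,
                             seed=3)
        net, dom, cat = generate(spec)
        positives = planted_heterotrimers(cat)
        from trimerpred.evaluation import negative_pool

        data = [LabeledTriplet(t, 1) for t in positives] + [
            LabeledTriplet(t, -1) for t in negative_pool(cat, net)[:6]
        ]
        model = fit_two_phase(data, net, dom)
        pure_trimer_rows = model.train_f2[: len(positives)]
        assert np.all(pure_trimer_rows[:, 8:] == 0.0)  # f2p, f2n, f2a all zero
        label, score = predict_two_phase(model, positives[0])
        assert np.isfinite(score)

    def test_sparse_bayes_second_classifier(self, planted):
        net, dom, data = planted
        from trimerpred.rvm import RVMModel

        model = fit_two_phase(
            data, net, dom, TwoPhaseConfig(second_classifier="sparse-bayes")
        )
        assert isinstance(model.phase2, RVMModel)
        pred, scores = predict_two_phase_many(model, [ex.triplet for ex in data])
        labels = np.array([ex.label for ex in data])
        assert np.mean(pred == labels) > 0.8

    def test_disconnected_test_triplet_rejected(self, planted):
        net, dom, data = planted
        model = fit_two_phase(data, net, dom)
        vs = sorted(net.vertices)
        with pytest.raises(ValueError, match="not connected"):
            # find three vertices with no edges among them
            from trimerpred.ppi_graph import is_connected_triplet

            for a in vs:
                for b in vs[::-1]:
                    t = None
                    if a != b and not net.has_edge(a, b):
                        c = next(
                            (v for v in vs if v not in (a, b)
                             and not net.has_edge(a, v) and not net.has_edge(b, v)),
                            None,
                        )
                        if c is not None:
                            t = ProteinTriplet.of(a, b, c)
                            break
                if t is not None:
                    break
            assert t is not None
            predict_two_phase(model, t)

    def test_phase2_invariant_on_all_training_rows(self, planted):
        net, dom, data = planted
        model = fit_two_phase(data, net, dom)
        f2p, f2n, f2a = model.train_f2[:, 8], model.train_f2[:, 9], model.train_f2[:, 10]
        assert np.all(f2n <= f2a + 1e-9)
        assert np.all(f2a <= f2p + 1e-9)

    def test_training_never_reads_heldout_labels(self, planted):
        # held-out triplets stay in the network (their graph structure may be
        # visited as neighbours) but their labels are booby-trapped: training
        # must complete without ever touching them
        net, dom, data = planted
        train = data[::2] + data[1::2][:4]  # both classes present

        class BoobyTrappedLabel:
            def __eq__(self, other):
                raise AssertionError("held-out label read during training")

            __req__ = __eq__

            def __int__(self):
                raise AssertionError("held-out label read during training")

        heldout = [
            object.__new__(LabeledTriplet) for _ in data[len(train):]
        ]
        for proxy, ex in zip(heldout, data[len(train):]):
            object.__setattr__(proxy, "triplet", ex.triplet)
            object.__setattr__(proxy, "label", BoobyTrappedLabel())

        model = fit_two_phase(train, net, dom)
        assert model.phase2 is not None
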