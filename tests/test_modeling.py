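"""The required bag-of-words linear backend and the metric suite, checked
against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fhirpipe import BackendSpec, LabelKind, Task, TaskLabel, evaluate, train
from fhirpipe.modeling import (
    AlignmentError,
    BagOfWordsLinearModel,
    SingleClassError,
    evaluate_binary,
    evaluate_multilabel,
)

from oracles import brute_binary_metrics, brute_multilabel_metrics


def _binary_labels(values):
    return [TaskLabel(Task.READMISSION, LabelKind.BINARY, bool(v)) for v in values]


SEPARABLE_TEXTS = ["alpha beta risk marker"] * 10 + ["alpha beta calm stable"] * 10
SEPARABLE_Y = [True] * 10 + [False] * 10


class TestTraining:
    def test_separable_set_perfect_training_accuracy(self):
        model = train(SEPARABLE_TEXTS, _binary_labels(SEPARABLE_Y),
                      LabelKind.BINARY)
        probs = model.predict_proba(SEPARABLE_TEXTS)
        report = evaluate_binary(SEPARABLE_Y, probs)
        assert report.accuracy == 1.0

    def test_deterministic_given_seed(self):
        a = train(SEPARABLE_TEXTS, _binary_labels(SEPARABLE_Y),
                  LabelKind.BINARY, BackendSpec(seed=5))
        b = train(SEPARABLE_TEXTS, _binary_labels(SEPARABLE_Y),
                  LabelKind.BINARY, BackendSpec(seed=5))
        assert np.array_equal(a.predict_proba(SEPARABLE_TEXTS),
                              b.predict_proba(SEPARABLE_TEXTS))

    def test_single_class_error_names_class(self):
        with pytest.raises(SingleClassError, match="positive"):
            train(["a"] * 5, _binary_labels([True] * 5), LabelKind.BINARY)

    def test_probabilities_are_logistic_of_scores(self):
        model = train(SEPARABLE_TEXTS, _binary_labels(SEPARABLE_Y),
                      LabelKind.BINARY)
        probs = model.predict_proba(SEPARABLE_TEXTS)
        scores = model.decision_scores(SEPARABLE_TEXTS)
        assert np.allclose(probs, 1.0 / (1.0 + np.exp(-scores)), atol=1e-12)

    def test_bounds_and_empty_input(self):
        model = train(SEPARABLE_TEXTS, _binary_labels(SEPARABLE_Y),
                      LabelKind.BINARY)
        probs = model.predict_proba(["gamma delta", "risk marker"])
        assert np.all((probs >= 0) & (probs <= 1))
        assert model.predict_proba([]).shape == (0,)

    def test_multilabel_one_vs_rest(self):
        texts = ["ct scan head", "mr spine", "ct scan chest", "us abdomen"]
        labels = [TaskLabel(Task.IMAGING, LabelKind.MULTILABEL, {"CT"}, ("CT", "MR")),
                  TaskLabel(Task.IMAGING, LabelKind.MULTILABEL, {"MR"}, ("CT", "MR")),
                  TaskLabel(Task.IMAGING, LabelKind.MULTILABEL, {"CT"}, ("CT", "MR")),
                  TaskLabel(Task.IMAGING, LabelKind.MULTILABEL, set(), ("CT", "MR"))]
        model = train(texts, labels, LabelKind.MULTILABEL,
                      label_space=("CT", "MR"))
        probs = model.predict_proba(texts)
        assert probs.shape == (4, 2)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_degenerate_label_gets_constant_probability(self):
        texts = ["a b", "c d", "e f"]
        labels = [TaskLabel(Task.IMAGING, LabelKind.MULTILABEL, set(), ("CT",))
                  for _ in texts]
        model = BagOfWordsLinearModel(LabelKind.MULTILABEL, label_space=("CT",))
        model.fit(texts, labels)
        probs = model.predict_proba(texts)
        assert np.all(probs > 0) and np.all(probs < 1)
        assert len(np.unique(probs)) == 1


class TestBinaryMetrics:
    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, FN=2, TN=4
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05]
        report = evaluate_binary(y, p)
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.6)
        assert report.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        report = evaluate_binary([1, 0, 1], [0.9, 0.1, 0.8])
        assert (report.accuracy, report.precision, report.recall,
                report.f1, report.roc_auc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        p = rng.random(50)
        base = evaluate_binary(y, p).roc_auc
        squashed = evaluate_binary(y, 1 / (1 + np.exp(-(5 * p - 2)))).roc_auc
        assert squashed == pytest.approx(base, abs=1e-12)

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(AlignmentError):
            evaluate_binary([1, 0], [0.5])


class TestAgainstBruteForce:
    def test_binary_agrees_to_1e12(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = np.round(rng.random(n), 3)  # rounded to provoke ties
            ours = evaluate_binary(y, p).to_dict()
            oracle = brute_binary_metrics(list(y), list(p))
            for key, expected in oracle.items():
                assert abs(ours[key] - expected) <= 1e-12, key

    def test_multilabel_agrees_to_1e12(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            n_labels = int(rng.integers(2, 8))
            k = int(rng.integers(1, n_labels + 1))
            Y = rng.integers(0, 2, (n, n_labels))
            P = np.round(rng.random((n, n_labels)), 2)
            ours = evaluate_multilabel(Y, P, k=k).to_dict()
            oracle = brute_multilabel_metrics(Y.tolist(), P.tolist(), k=k)
            for key, expected in oracle.items():
                assert abs(ours[key] - expected) <= 1e-12, key

    def test_topk_accuracy_monotone_in_k_exhaustive(self):
        """On every 0/1 truth pattern over <=5 labels, top-k accuracy never
        decreases as k grows."""
        import itertools

        rng = np.random.default_rng(7)
        for n_labels in (2, 3, 5):
            patterns = list(itertools.product([0, 1], repeat=n_labels))
            Y = np.array(patterns)
            P = np.round(rng.random(Y.shape), 2)
            accs = [evaluate_multilabel(Y, P, k=k).topk_accuracy
                    for k in range(1, n_labels + 1)]
            assert all(a <= b + 1e-15 for a, b in zip(accs, accs[1:]))
            assert accs[-1] == 1.0  # k = |label_space| contains every label


class TestMultilabelMetrics:
    def test_macro_f1_is_mean_of_per_class_column(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 2, (20, 6))
        P = rng.random((20, 6))
        report = evaluate_multilabel(Y, P, label_space=[f"L{i}" for i in range(6)])
        per_class_f1 = [row["f1"] for row in report.per_class]
        assert report.macro_f1 == pytest.approx(sum(per_class_f1) / 6, abs=1e-15)

    def test_absent_class_counts_zero(self):
        Y = np.array([[1, 0], [1, 0]])
        P = np.array([[0.9, 0.1], [0.8, 0.2]])
        report = evaluate_multilabel(Y, P)
        assert report.macro_f1 == pytest.approx(0.5)  # class 2 contributes 0

    def test_k_clamped_with_warning(self):
        Y = np.array([[1, 0], [0, 1]])
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        with pytest.warns(UserWarning, match="clamped"):
            report = evaluate_multilabel(Y, P, k=10)
        assert report.k == 2

    def test_dispatch(self):
        report = evaluate([1, 0], [0.9, 0.1], LabelKind.BINARY)
        assert report.f1 == 1.0
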