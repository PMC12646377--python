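"""Train and evaluate classifiers on serialized text samples.

The required backend is desk-scale and CPU-only: hashed bag-of-words
features with L2-regularized logistic scoring, one-vs-rest for multilabel
tasks. It is deterministic given its seed and trains in seconds at the
problem sizes this package targets; a transformer encoder is an optional
adapter keyed by a checkpoint-name string and is intentionally not bundled.

The metric suite mirrors the usual clinical-ML report: accuracy, precision,
recall, F1 and ROC AUC for binary tasks; exact-match accuracy, macro
precision/recall/F1 over the full label space (classes that never occur
contribute 0), and top-k variants for multilabel tasks. "Top-k accuracy"
counts a sample as a hit iff every true label is among the k
highest-scoring labels (an "any label" variant is available); top-k macro
metrics are computed from the binarized in-top-k predictions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .types import LabelKind, TaskLabel


class SingleClassError(ValueError):
    """Binary training set contains only one class."""


class AlignmentError(ValueError):
    """Prediction/label shapes or label spaces do not line up."""


@dataclasses.dataclass
class BackendSpec:
    kind: str = "bag_of_words_linear"
    hyperparams: dict = dataclasses.field(default_factory=dict)
    model_name: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("bag_of_words_linear", "transformer_encoder"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.kind == "transformer_encoder":
            raise NotImplementedError(
                "the transformer_encoder adapter is not bundled; use the "
                "required bag_of_words_linear backend"
            )

    @property
    def C(self) -> float:
        return float(self.hyperparams.get("C", 1.0))

    @property
    def max_iter(self) -> int:
        return int(self.hyperparams.get("max_iter", 200))

    @property
    def n_features(self) -> int:
        return int(self.hyperparams.get("n_features", 2**18))

    @property
    def threshold(self) -> float:
        return float(self.hyperparams.get("threshold", 0.5))

    @property
    def class_weight(self) -> Optional[str]:
        return self.hyperparams.get("class_weight", "balanced")

    @property
    def solver(self) -> str:
        return self.hyperparams.get("solver", "liblinear")


def binarize_labels(labels: Sequence[TaskLabel],
                    label_space: Sequence[str]) -> np.ndarray:
    """Multilabel TaskLabels -> (n_samples, n_labels) 0/1 matrix."""
    index = {code: j for j, code in enumerate(label_space)}
    out = np.zeros((len(labels), len(label_space)), dtype=np.int64)
    for i, label in enumerate(labels):
        for code in label.value:
            j = index.get(code)
            if j is not None:
                out[i, j] = 1
    return out


class _ConstantProbability:
    """Fallback scorer for a label with a single class in training."""

    def __init__(self, prevalence: float):
        self.prevalence = prevalence

    def predict_proba(self, X):
        n = X.shape[0]
        p = np.full(n, self.prevalence)
        return np.column_stack([1 - p, p])


class BagOfWordsLinearModel:
    """Hashed bag-of-words + L2 logistic regression, one-vs-rest for
    multilabel. Probabilities are the logistic transform of the linear
    scores; deterministic given the backend seed."""

    def __init__(self, kind: LabelKind, backend: Optional[BackendSpec] = None,
                 label_space: tuple[str, ...] = ()):
        self.kind = LabelKind(kind)
        self.backend = backend or BackendSpec()
        self.label_space = tuple(label_space)
        self.vectorizer = HashingVectorizer(
            n_features=self.backend.n_features, alternate_sign=False, norm=None,
            lowercase=True,
        )
        self._estimators: list = []

    def fit(self, texts: Sequence[str], labels: Sequence[TaskLabel]) -> "BagOfWordsLinearModel":
        if len(texts) == 0:
            raise ValueError("empty training set")
        if len(texts) != len(labels):
            raise AlignmentError("texts and labels differ in length")
        X = self.vectorizer.transform(texts)
        if self.kind is LabelKind.BINARY:
            y = np.array([bool(lbl.value) for lbl in labels], dtype=np.int64)
            classes = np.unique(y)
            if classes.size < 2:
                name = "positive" if classes[0] == 1 else "negative"
                raise SingleClassError(
                    f"binary training set contains only the {name} class"
                )
            est = LogisticRegression(
                C=self.backend.C, max_iter=self.backend.max_iter,
                class_weight=self.backend.class_weight,
                solver=self.backend.solver, random_state=self.backend.seed,
            )
            est.fit(X, y)
            self._estimators = [est]
        else:
            if not self.label_space:
                raise ValueError("multilabel training requires a fixed label_space")
            Y = binarize_labels(labels, self.label_space)
            self._estimators = []
            for j in range(Y.shape[1]):
                col = Y[:, j]
                if col.min() == col.max():
                    # degenerate label: smoothed prevalence, never 0 or 1
                    prevalence = (col.sum() + 0.5) / (len(col) + 1.0)
                    self._estimators.append(_ConstantProbability(prevalence))
                else:
                    est = LogisticRegression(
                        C=self.backend.C, max_iter=self.backend.max_iter,
                        solver=self.backend.solver,
                        random_state=self.backend.seed,
                    )
                    est.fit(X, col)
                    self._estimators.append(est)
        return self

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """Binary -> (n,) positive-class probabilities; multilabel ->
        (n, n_labels), all values in [0, 1]."""
        if not self._estimators:
            raise ValueError("model is not fitted")
        if len(texts) == 0:
            n_cols = 1 if self.kind is LabelKind.BINARY else len(self.label_space)
            empty = np.zeros((0, n_cols))
            return empty[:, 0] if self.kind is LabelKind.BINARY else empty
        X = self.vectorizer.transform(texts)
        if self.kind is LabelKind.BINARY:
            return self._estimators[0].predict_proba(X)[:, 1]
        cols = [est.predict_proba(X)[:, 1] for est in self._estimators]
        return np.column_stack(cols)

    def decision_scores(self, texts: Sequence[str]) -> np.ndarray:
        """Raw linear scores (binary backend only)."""
        X = self.vectorizer.transform(texts)
        return self._estimators[0].decision_function(X)


def train(
    texts: Sequence[str],
    labels: Sequence[TaskLabel],
    kind: LabelKind,
    backend: Optional[BackendSpec] = None,
    label_space: tuple[str, ...] = (),
) -> BagOfWordsLinearModel:
    """Fit the required backend on the training split."""
    model = BagOfWordsLinearModel(kind, backend, label_space)
    return model.fit(texts, labels)


# --------------------------------------------------------------------------
# metrics


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    roc_auc: Optional[float] = None
    macro_precision: Optional[float] = None
    macro_recall: Optional[float] = None
    macro_f1: Optional[float] = None
    topk_accuracy: Optional[float] = None
    topk_macro_precision: Optional[float] = None
    topk_macro_recall: Optional[float] = None
    topk_macro_f1: Optional[float] = None
    k: Optional[int] = None
    per_class: Optional[list[dict]] = None
    loss: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return precision, recall, f1


def log_loss_binary(y_true: np.ndarray, probs: np.ndarray,
                    eps: float = 1e-12) -> float:
    p = np.clip(np.asarray(probs, dtype=float), eps, 1 - eps)
    y = np.asarray(y_true, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def evaluate_binary(y_true: Sequence[int], probs: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    y = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise AlignmentError("predictions and labels differ in length")
    pred = (p >= threshold).astype(np.int64)
    tp = float(np.sum((pred == 1) & (y == 1)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    precision, recall, f1 = _prf(tp, fp, fn)
    accuracy = (tp + tn) / len(y) if len(y) else 0.0
    auc = None
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, p))
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        roc_auc=auc, loss=log_loss_binary(y, p) if len(y) else None,
    )


def topk_indices(probs: np.ndarray, k: int) -> list[set]:
    """Per-sample sets of the k highest-scoring label indices; ties broken
    toward the lower index (stable sort on descending score)."""
    order = np.argsort(-probs, axis=1, kind="stable")
    return [set(row[:k].tolist()) for row in order]


def evaluate_multilabel(
    y_true: np.ndarray,
    probs: np.ndarray,
    threshold: float = 0.5,
    k: int = 10,
    topk_mode: str = "all",
    label_space: Sequence[str] = (),
) -> MetricsReport:
    Y = np.asarray(y_true, dtype=np.int64)
    P = np.asarray(probs, dtype=float)
    if Y.shape != P.shape:
        raise AlignmentError("predictions and labels differ in shape")
    n, n_labels = Y.shape
    if k > n_labels:
        warnings.warn(f"k={k} exceeds label space size {n_labels}; clamped")
        k = n_labels
    if k < 1:
        raise ValueError("k must be >= 1")
    pred = (P >= threshold).astype(np.int64)

    accuracy = float(np.mean(np.all(pred == Y, axis=1))) if n else 0.0

    def macro(prediction: np.ndarray) -> tuple[float, float, float, list[dict]]:
        precisions, recalls, f1s, table = [], [], [], []
        for j in range(n_labels):
            tp = float(np.sum((prediction[:, j] == 1) & (Y[:, j] == 1)))
            fp = float(np.sum((prediction[:, j] == 1) & (Y[:, j] == 0)))
            fn = float(np.sum((prediction[:, j] == 0) & (Y[:, j] == 1)))
            p_j, r_j, f_j = _prf(tp, fp, fn)
            precisions.append(p_j)
            recalls.append(r_j)
            f1s.append(f_j)
            table.append({
                "label": label_space[j] if j < len(label_space) else str(j),
                "precision": p_j, "recall": r_j, "f1": f_j,
                "support": int(Y[:, j].sum()),
            })
        m = n_labels if n_labels else 1
        return (sum(precisions) / m, sum(recalls) / m, sum(f1s) / m, table)

    macro_p, macro_r, macro_f, per_class = macro(pred)

    top = topk_indices(P, k)
    if topk_mode == "all":
        hits = [set(np.flatnonzero(Y[i]).tolist()) <= top[i] for i in range(n)]
    elif topk_mode == "any":
        hits = [bool(set(np.flatnonzero(Y[i]).tolist()) & top[i])
                or not Y[i].any() for i in range(n)]
    else:
        raise ValueError(f"unknown topk_mode {topk_mode!r}")
    topk_accuracy = float(np.mean(hits)) if n else 0.0
    topk_pred = np.zeros_like(pred)
    for i, indices in enumerate(top):
        topk_pred[i, list(indices)] = 1
    topk_p, topk_r, topk_f, _ = macro(topk_pred)

    eps = 1e-12
    P_clipped = np.clip(P, eps, 1 - eps)
    loss = float(-np.mean(Y * np.log(P_clipped) + (1 - Y) * np.log(1 - P_clipped))) if n else None

    return MetricsReport(
        accuracy=accuracy,
        macro_precision=macro_p, macro_recall=macro_r, macro_f1=macro_f,
        topk_accuracy=topk_accuracy, topk_macro_precision=topk_p,
        topk_macro_recall=topk_r, topk_macro_f1=topk_f, k=k,
        per_class=per_class, loss=loss,
    )


def evaluate(
    y_true,
    probs,
    kind: LabelKind,
    threshold: float = 0.5,
    k: int = 10,
    topk_mode: str = "all",
    label_space: Sequence[str] = (),
) -> MetricsReport:
    """Dispatch to the binary or multilabel metric suite."""
    if LabelKind(kind) is LabelKind.BINARY:
        return evaluate_binary(y_true, probs, threshold)
    return evaluate_multilabel(y_true, probs, threshold, k, topk_mode, label_space)
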