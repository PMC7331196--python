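"""Classifier harness: the four model families, observation scoring,
single-hit response aggregation, threshold sweeping and metrics.

Four families are compared: linear discriminant analysis (LDA),
quadratic discriminant analysis (QDA), a linear support vector machine
(LSVM) with hinge loss and a x35 weight on the under-represented
stepping observations, and a one-hidden-layer neural network (NN) with
five to eight sigmoid units trained by cross-entropy.

The prediction score is the stepping posterior probability (LDA, QDA,
NN) or the signed distance to the decision boundary (LSVM).  A response
is predicted stepping when at least one observation in its window scores
above the threshold — equivalently when the window's maximum score does.
The threshold itself is chosen on the validation set to maximize
response-level accuracy, breaking ties by the larger sensitivity +
specificity sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

__all__ = [
    "ClassifierSpec",
    "PerformanceMetrics",
    "confusion_metrics",
    "train",
    "score",
    "classify_response",
    "evaluate_windows",
    "sweep_threshold",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier family.

    ``hidden_neurons`` applies to the NN only (one hidden layer, 5-8
    units); ``step_class_weight`` to the LSVM only (weight on stepping
    observations relative to non-stepping ones); ``C`` is the LSVM
    regularization constant.
    """

    kind: str  # {"LDA", "QDA", "LSVM", "NN"}
    hidden_neurons: int = 8
    step_class_weight: float = 35.0
    C: float = 1.0
    qda_reg: float = 1e-6
    weight_decay: float = 0.1  # NN L2 penalty; keeps the sigmoid units out of saturation
    max_epochs: int = 500
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("LDA", "QDA", "LSVM", "NN"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "NN" and not 1 <= self.hidden_neurons <= 64:
            raise ValueError("hidden_neurons out of range")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(
            kind=self.kind,
            hidden_neurons=self.hidden_neurons,
            step_class_weight=self.step_class_weight,
            C=self.C,
            qda_reg=self.qda_reg,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            init_seed=seed,
        )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Response-level confusion counts and derived rates."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


def confusion_metrics(predicted_step: np.ndarray, labels: np.ndarray) -> PerformanceMetrics:
    predicted_step = np.asarray(predicted_step, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    return PerformanceMetrics(
        tp=int(np.sum(predicted_step & labels)),
        fn=int(np.sum(~predicted_step & labels)),
        tn=int(np.sum(~predicted_step & ~labels)),
        fp=int(np.sum(predicted_step & ~labels)),
    )


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis()
    if spec.kind == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=spec.qda_reg)
    if spec.kind == "LSVM":
        return LinearSVC(
            loss="hinge",
            C=spec.C,
            class_weight={1: spec.step_class_weight, 0: 1.0},
            max_iter=20000,
            random_state=spec.init_seed,
        )
    return MLPClassifier(
        hidden_layer_sizes=(spec.hidden_neurons,),
        activation="logistic",
        solver="lbfgs",
        alpha=spec.weight_decay,
        max_iter=spec.max_epochs,
        random_state=spec.init_seed,
    )


def train(spec: ClassifierSpec, observations: np.ndarray, labels: np.ndarray):
    """Fit one classifier on standardized observations.

    ``labels`` is a 0/1 vector (1 = stepping).  Non-convergence of the
    NN raises a warning and returns the best model found.
    """
    observations = np.asarray(observations, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    model = _make_estimator(spec)
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        model.fit(observations, labels)
    return model


def score(model, observations: np.ndarray) -> np.ndarray:
    """Prediction scores, monotone in stepping likelihood.

    Posterior probability of the stepping class for LDA/QDA/NN; signed
    decision value for the LSVM.
    """
    observations = np.atleast_2d(np.asarray(observations, dtype=float))
    n_expected = getattr(model, "n_features_in_", observations.shape[1])
    if observations.shape[1] != n_expected:
        raise ValueError(
            f"observation has {observations.shape[1]} features, model expects {n_expected}"
        )
    if isinstance(model, LinearSVC):
        return model.decision_function(observations)
    proba = model.predict_proba(observations)
    step_col = int(np.nonzero(model.classes_ == 1)[0][0])
    return proba[:, step_col]


def classify_response(scores: np.ndarray, threshold: float) -> str:
    """Single-hit aggregation: stepping iff any score exceeds the threshold."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty observation window")
    return "stepping" if np.max(scores) > threshold else "non-stepping"


def window_max_scores(model, windows: dict[str, tuple[np.ndarray, int]]):
    """Max observation score and label per response window."""
    ids = sorted(windows)
    max_scores = np.array([np.max(score(model, windows[rid][0])) for rid in ids])
    labels = np.array([windows[rid][1] for rid in ids], dtype=int)
    return ids, max_scores, labels


def sweep_threshold(
    max_scores: np.ndarray, labels: np.ndarray
) -> tuple[float, PerformanceMetrics]:
    """Accuracy-maximizing score threshold at the response level.

    Candidates are the midpoints of the sorted per-response maximum
    scores plus open-ended sentinels.  Ties on accuracy are broken by the
    larger sensitivity + specificity sum, then by the larger (more
    specific) threshold.
    """
    max_scores = np.asarray(max_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least one response of each class")
    uniq = np.unique(max_scores)
    candidates = [float(uniq[0]) - 1.0]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates.append(float(uniq[-1]) + 1.0)
    best = None
    for thr in candidates:
        pred = max_scores > thr
        metrics = confusion_metrics(pred, labels)
        key = (metrics.accuracy, metrics.sensitivity + metrics.specificity, thr)
        if best is None or key > best[0]:
            best = (key, thr, metrics)
    return best[1], best[2]


def evaluate_windows(
    model, windows: dict[str, tuple[np.ndarray, int]], threshold: float
) -> PerformanceMetrics:
    """Response-level metrics at a fixed score threshold."""
    _, max_scores, labels = window_max_scores(model, windows)
    return confusion_metrics(max_scores > threshold, labels)
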