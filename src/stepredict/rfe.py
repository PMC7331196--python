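"""Recursive feature elimination with repeat-averaged validation accuracy.

At each stage every leave-one-out feature subset is retrained and scored
on the validation responses (threshold-swept, response-level accuracy);
for neural networks the accuracy is averaged over several random
restarts.  The feature absent from the best subset is the least
important one and is eliminated; the procedure repeats until a single
feature remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, sweep_threshold, train, window_max_scores

__all__ = ["RfeTrace", "run_rfe", "subset_accuracy"]


@dataclass
class RfeTrace:
    """Elimination order with the best accuracy at every stage."""

    eliminated: list[str] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    survivor: str = ""

    @property
    def ranking(self) -> list[str]:
        """Features from least to most important (survivor last)."""
        return [*self.eliminated, self.survivor]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": range(1, len(self.eliminated) + 1),
                "eliminated_feature": self.eliminated,
                "best_validation_accuracy": self.accuracies,
            }
        )


def _subset_windows(windows: dict, columns: np.ndarray) -> dict:
    return {rid: (X[:, columns], y) for rid, (X, y) in windows.items()}


def subset_accuracy(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    val_windows: dict,
    n_repeats: int,
    seeds: list[int],
) -> tuple[float, float]:
    """Repeat-averaged threshold-swept validation accuracy of one subset.

    Returns ``(mean accuracy, mean sensitivity + specificity)``.  Only
    neural networks use more than one repeat; the other families are
    deterministic fits.
    """
    reps = n_repeats if spec.kind == "NN" else 1
    accs, sums = [], []
    for r in range(reps):
        model = train(spec.with_seed(seeds[r]), X_train, y_train)
        _, max_scores, labels = window_max_scores(model, val_windows)
        _, metrics = sweep_threshold(max_scores, labels)
        accs.append(metrics.accuracy)
        sums.append(metrics.sensitivity + metrics.specificity)
    return float(np.mean(accs)), float(np.mean(sums))


def run_rfe(
    spec: ClassifierSpec,
    feature_names: list[str],
    X_train: np.ndarray,
    y_train: np.ndarray,
    val_windows: dict[str, tuple[np.ndarray, int]],
    n_repeats: int = 10,
    seed: int = 0,
) -> RfeTrace:
    """Recursive feature elimination down to a single surviving feature.

    ``X_train`` columns and each validation window's columns must align
    with ``feature_names``.  The seed schedule is indexed by stage,
    subset and repeat, so reruns with the same seed are reproducible.
    Ties between equally accurate subsets are broken by the larger
    sensitivity + specificity sum, then by feature-name order.
    """
    names = list(feature_names)
    if len(names) < 2:
        raise ValueError("need at least two features to eliminate one")
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[1] != len(names):
        raise ValueError("X_train column count does not match feature_names")

    active = list(range(len(names)))
    trace = RfeTrace()
    rng = np.random.default_rng(seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=(len(names), len(names), max(n_repeats, 1)))

    for stage in range(len(names) - 1):
        results = []
        for j, drop in enumerate(active):
            keep = np.array([c for c in active if c != drop])
            seeds = [int(s) for s in stage_seeds[stage, j]]
            try:
                acc, ss = subset_accuracy(
                    spec,
                    X_train[:, keep],
                    y_train,
                    _subset_windows(val_windows, keep),
                    n_repeats,
                    seeds,
                )
            except ValueError as exc:
                warnings.warn(f"subset without {names[drop]} skipped: {exc}", stacklevel=2)
                continue
            results.append((acc, ss, -active.index(drop), drop))
        if not results:
            raise RuntimeError("every leave-one-out subset was degenerate")
        # best subset: highest accuracy, then highest sens+spec, then
        # first feature in the fixed name order
        acc, _, _, drop = max(results)
        trace.eliminated.append(names[drop])
        trace.accuracies.append(acc)
        active.remove(drop)
    trace.survivor = names[active[0]]
    return trace
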