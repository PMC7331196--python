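"""Conventional model-based step predictors: stability boundary,
extrapolated centre of mass (XCoM), and CoM-time-to-boundary (TTB).

All three reason about the anteroposterior CoM state relative to the
base of support (BoS).  The stability boundary is the line through
(toe, 0) and (heel, 0.45 1/s) in (CoM position, height-normalized CoM
velocity) space.  The XCoM is ``xi = x_com + xd_com / sqrt(g/l)``; a step
is predicted when it passes the anterior BoS limit.  The TTB is the time
for the CoM to reach the BoS edge at its current velocity (infinite for
non-forward motion); a step is predicted when it falls below a threshold
optimized for accuracy.

A response-level prediction mirrors the classifier aggregation rule: a
response is predicted stepping if any sample inside its observation
window triggers the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PerformanceMetrics, confusion_metrics

__all__ = [
    "ConventionalParams",
    "stability_boundary_predict",
    "xcom",
    "ttb",
    "optimize_ttb_threshold",
    "BOS_SCALE_GRID",
]

G = 9.81
BOUNDARY_HEEL_VELOCITY = 0.45  # 1/s, height-normalized velocity limit above the heel

#: BoS fractions tried when sweeping the effective XCoM boundary.
BOS_SCALE_GRID = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass(frozen=True)
class ConventionalParams:
    """Geometry and tuning of the conventional predictors."""

    g: float = G
    l: float | None = None  # pendulum length; defaults to the subject's h_com
    bos_scale: float = 1.0  # fraction of the foot length used as effective BoS
    ttb_threshold: float = 0.5  # s

    def __post_init__(self) -> None:
        if not 0 < self.bos_scale <= 1:
            raise ValueError("bos_scale must be in (0, 1]")


def stability_boundary_predict(
    x_com: np.ndarray, xd_com: np.ndarray, height: float, x_heel: float, x_toe: float
) -> np.ndarray:
    """Step prediction from the CoM-state stability boundary.

    The admissible height-normalized velocity falls linearly from 0.45
    1/s above the heel to 0 above the toe; states above the line predict
    a step.
    """
    if not x_heel < x_toe:
        raise ValueError("x_heel must lie behind x_toe")
    limit = BOUNDARY_HEEL_VELOCITY * (x_toe - np.asarray(x_com)) / (x_toe - x_heel)
    return np.asarray(xd_com) / height > limit


def xcom(x_com: np.ndarray, xd_com: np.ndarray, g: float = G, l: float = 1.0) -> np.ndarray:
    """Extrapolated centre of mass ``xi = x_com + xd_com / sqrt(g/l)``."""
    if l <= 0:
        raise ValueError("pendulum length must be positive")
    return np.asarray(x_com) + np.asarray(xd_com) / np.sqrt(g / l)


def xcom_predict(
    x_com: np.ndarray,
    xd_com: np.ndarray,
    x_heel: float,
    foot_length: float,
    params: ConventionalParams,
    l: float,
) -> np.ndarray:
    """Step predicted when the XCoM passes the effective anterior BoS limit."""
    limit = x_heel + params.bos_scale * foot_length
    return xcom(x_com, xd_com, params.g, l) > limit


def ttb(x_com: np.ndarray, xd_com: np.ndarray, x_bos: float) -> np.ndarray:
    """CoM-time-to-boundary: ``(x_bos - x_com)/xd_com`` for forward motion,
    infinite otherwise."""
    x = np.asarray(x_com, dtype=float)
    v = np.asarray(xd_com, dtype=float)
    out = np.full(np.broadcast(x, v).shape, np.inf)
    forward = v > 0
    with np.errstate(divide="ignore"):
        np.divide(x_bos - x, v, out=out, where=forward)
    return out


def optimize_ttb_threshold(
    min_tau: np.ndarray, labels: np.ndarray
) -> tuple[float, PerformanceMetrics]:
    """Accuracy-maximizing TTB threshold over per-response minimum tau.

    A response is predicted stepping when its minimum time-to-boundary is
    below the threshold.  Candidates are the midpoints of the sorted
    minimum-tau values (plus open-ended sentinels); ties on accuracy are
    broken by the larger sensitivity + specificity sum, then by the
    smaller (more conservative) threshold.
    """
    min_tau = np.asarray(min_tau, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least one response of each class")
    finite = min_tau[np.isfinite(min_tau)]
    uniq = np.unique(finite)
    candidates = [0.0]
    candidates += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    if len(uniq):
        candidates.append(float(uniq[-1]) + 1.0)
    best = None
    for thr in candidates:
        pred = min_tau < thr
        metrics = confusion_metrics(pred, labels)
        key = (metrics.accuracy, metrics.sensitivity + metrics.specificity, -thr)
        if best is None or key > best[0]:
            best = (key, thr, metrics)
    return best[1], best[2]
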