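"""Response labeling: step detection, event times, prediction time steps,
screening of unnatural trials, and dataset splitting.

A response counts as a reactive step when (1) the vertical ground
reaction force under one foot drops below 20 N, (2) this happens within
two seconds of perturbation onset, and (3) the step length is at least
20% of the subject's foot length.  If (1) holds but (2) and/or (3) fail
the trial is excluded from further analysis.  Toe-off (TO) is the onset
of the zero-force phase; step-leg unloading (SLU) is found by scanning
the stepping-foot force backward from TO to the onset of the final
monotone decline.

Seven prediction time steps bound the observation windows: two before
SLU, SLU itself, three between SLU and TO, and TO, equally spaced by
``(t_TO - t_SLU)/4`` and snapped to the 100 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response import ProcessedResponse

__all__ = [
    "StepEvents",
    "ScreenConfig",
    "TIMESTEP_KEYS",
    "detect_step",
    "detect_slu",
    "prediction_timesteps",
    "screen_response",
    "split_dataset",
    "build_observation_set",
    "evaluation_windows",
]

FZ_STEP_THRESHOLD = 20.0  # N
FZ_ZERO = 1.0  # N, force considered "reached zero"
MAX_STEP_DELAY = 2.0  # s after perturbation onset
MIN_STEP_FRACTION = 0.20  # of foot length
SLU_RISE_TOLERANCE = 2.0  # N rise allowed inside the "monotone" decline

TIMESTEP_KEYS = ("SLU-2", "SLU-1", "SLU", "TO-3", "TO-2", "TO-1", "TO")


@dataclass
class StepEvents:
    """Detected events of a stepping response (times on the common clock)."""

    t_TO: float
    t_SLU: float
    stepping_foot: str  # "l" or "r"
    step_length: float


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds operationalizing the trial-screening rules.

    The lean limit is stated by the screening protocol (0.03 m); the
    sway, weight-distribution and heel-lift thresholds quantify rules
    that are otherwise qualitative.
    """

    max_lean: float = 0.03  # m, |baseline CoM lean|
    max_sway_rms: float = 0.02  # m/s, baseline CoM-velocity RMS
    min_foot_share: float = 0.40  # fraction of body weight per foot at onset
    heel_lift_front_fraction: float = 0.20  # front part of the foot
    heel_lift_duration: float = 0.5  # s of CoP dwell implying heel lift


def _grid_round(time: float, step: float = 0.01) -> float:
    """Round to the 100 Hz grid, half away from zero."""
    scaled = time / step
    return float(np.copysign(np.floor(np.abs(scaled) + 0.5), scaled) * step)


def detect_step(response: ProcessedResponse) -> tuple[str, StepEvents | None]:
    """Classify a response as stepping / non-stepping / excluded.

    Returns ``(label, events)``; ``events`` is only set for stepping
    responses.  The toe-off time is the first sample where the unloading
    foot's force reaches (near) zero, refined from the first sub-20 N
    sample.
    """
    for ch in ("fz_l", "fz_r"):
        if ch not in response.channels:
            raise ValueError(f"missing per-foot force channel {ch}")
    t = response.t
    post = t >= response.onset
    candidates = []
    for foot in ("l", "r"):
        fz = response.channels[f"fz_{foot}"]
        below = post & (fz < FZ_STEP_THRESHOLD)
        if np.any(below):
            candidates.append((t[np.argmax(below)], foot))
    if not candidates:
        return "non-stepping", None
    t_cross, foot = min(candidates)
    if t_cross - response.onset > MAX_STEP_DELAY:
        return "excluded", None

    fz = response.channels[f"fz_{foot}"]
    i_cross = response.sample_index(t_cross)
    # refine to the zero-force onset
    after = np.nonzero(fz[i_cross:] <= FZ_ZERO)[0]
    i_to = i_cross + int(after[0]) if len(after) else i_cross
    t_to = t[i_to]
    if t_to - response.onset > MAX_STEP_DELAY:
        return "excluded", None

    step_length = _step_length(response, foot, i_to)
    if step_length < MIN_STEP_FRACTION * response.subject.foot_length:
        return "excluded", None

    t_slu = detect_slu(response, t_to, foot)
    return "stepping", StepEvents(
        t_TO=float(t_to), t_SLU=float(t_slu), stepping_foot=foot, step_length=step_length
    )


def _step_length(response: ProcessedResponse, foot: str, i_to: int) -> float:
    """Anteroposterior ankle displacement from baseline to first ground
    contact after toe-off."""
    t = response.t
    ankle = response.channels[f"x_ankle_{foot}"]
    fz = response.channels[f"fz_{foot}"]
    baseline = (t >= response.onset - 2.0) & (t < response.onset)
    x0 = float(np.mean(ankle[baseline]))
    reloaded = np.nonzero(fz[i_to:] > FZ_STEP_THRESHOLD)[0]
    i_land = i_to + int(reloaded[0]) if len(reloaded) else len(t) - 1
    return float(ankle[i_land] - x0)


def detect_slu(response: ProcessedResponse, t_to: float, foot: str | None = None) -> float:
    """Onset of the final monotone decline of the stepping-foot force.

    Scans backward from toe-off while the force keeps rising (small dips
    up to ``SLU_RISE_TOLERANCE`` are absorbed) and returns the time of
    the maximum over the scanned stretch — the last local peak before the
    force falls to zero.
    """
    if foot is None:
        foot = _lighter_foot(response, t_to)
    fz = response.channels[f"fz_{foot}"]
    i_to = response.sample_index(t_to)
    if i_to == 0:
        raise ValueError("toe-off at the first sample; no decline to scan")
    i = i_to
    peak = fz[i_to]
    i_peak = i_to
    while i > 0:
        prev = fz[i - 1]
        if prev < peak - SLU_RISE_TOLERANCE:
            break
        i -= 1
        if prev > peak:
            peak = prev
            i_peak = i
    if i == 0:
        warnings.warn(
            f"{response.response_id}: force declines monotonically from trial start; "
            "SLU set to the first sample",
            stacklevel=2,
        )
        return float(response.t[0])
    # latest admissible decline onset: walk forward past any near-peak
    # plateau (samples within the rise tolerance of the peak)
    j = i_peak
    while j + 1 < i_to and fz[j + 1] >= peak - SLU_RISE_TOLERANCE:
        j += 1
    return float(response.t[j])


def _lighter_foot(response: ProcessedResponse, t_to: float) -> str:
    i = response.sample_index(t_to)
    return "l" if response.channels["fz_l"][i] <= response.channels["fz_r"][i] else "r"


def prediction_timesteps(t_slu: float, t_to: float) -> dict[str, float]:
    """The seven prediction time steps for one stepping response.

    Spacing is a quarter of the SLU-to-TO interval; times are snapped to
    the nearest hundredth of a second (the 100 Hz motion grid).
    """
    if not t_slu < t_to:
        raise ValueError(f"t_SLU ({t_slu}) must precede t_TO ({t_to})")
    delta = (t_to - t_slu) / 4.0
    raw = [t_slu - 2 * delta, t_slu - delta] + [t_slu + k * delta for k in range(5)]
    return {key: _grid_round(val) for key, val in zip(TIMESTEP_KEYS, raw)}


def screen_response(
    response: ProcessedResponse,
    is_step: bool,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[str, str | None]:
    """Keep or dismiss a trial based on its pre-perturbation behaviour.

    Dismissal reasons: forward/backward lean beyond 0.03 m, excessive
    baseline sway, uneven weight distribution at onset, or sustained
    forward CoP dwell without a step (heel-lift proxy).
    """
    t = response.t
    baseline = (t >= response.onset - 2.0) & (t < response.onset)
    if not np.any(baseline):
        raise ValueError("baseline window missing")
    lean = float(np.mean(response.channels["x_com"][baseline]))
    if abs(lean) > config.max_lean:
        return "dismiss", "lean"
    sway = float(np.sqrt(np.mean(response.channels["xd_com"][baseline] ** 2)))
    if sway > config.max_sway_rms:
        return "dismiss", "sway"
    i0 = response.sample_index(response.onset)
    fz_l, fz_r = response.channels["fz_l"][i0], response.channels["fz_r"][i0]
    total = fz_l + fz_r
    if total <= 0 or min(fz_l, fz_r) / total < config.min_foot_share:
        return "dismiss", "uneven-load"
    if not is_step:
        front = (
            response.subject.x_toe
            - config.heel_lift_front_fraction * response.subject.foot_length
        )
        post = (t >= response.onset) & (t <= response.onset + 4.0)
        cop = response.channels["cop_x"][post]
        dwell = np.count_nonzero(np.nan_to_num(cop, nan=-np.inf) > front) / 100.0
        if dwell > config.heel_lift_duration:
            return "dismiss", "heel-lift"
    return "keep", None


def split_dataset(labels: pd.DataFrame, seed: int) -> pd.Series:
    """Assign screened responses to train / validation / test.

    ``labels`` needs columns ``response_id``, ``subject_id`` and
    ``label`` (stepping / non-stepping).  Within every subject-class
    stratum 15% goes to the test set first, then 70% / 30% of the
    remainder to training / validation, conserving per-subject class
    ratios.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=labels["response_id"], dtype=object, name="split")
    for (_, _), group in labels.groupby(["subject_id", "label"]):
        ids = group["response_id"].to_numpy().copy()
        if len(ids) < 2:
            warnings.warn(
                "stratum with fewer than two responses; best-effort assignment",
                stacklevel=2,
            )
        rng.shuffle(ids)
        n = len(ids)
        n_test = int(round(0.15 * n))
        n_train = int(round(0.70 * (n - n_test)))
        for rid in ids[:n_test]:
            assignment[rid] = "test"
        for rid in ids[n_test : n_test + n_train]:
            assignment[rid] = "train"
        for rid in ids[n_test + n_train :]:
            assignment[rid] = "validation"
    return assignment


def build_observation_set(
    feature_table: pd.DataFrame,
    labels: pd.DataFrame,
    timestep: str,
) -> pd.DataFrame:
    """Labeled training observations for one prediction time step.

    Non-stepping responses contribute every 100 Hz observation from
    perturbation onset to onset + 4 s; each stepping response contributes
    exactly one observation, at its own prediction time step.
    """
    if timestep not in TIMESTEP_KEYS:
        raise ValueError(f"unknown prediction time step {timestep!r}")
    merged = feature_table.merge(
        labels[["response_id", "label", "onset", f"t_{timestep}"]], on="response_id"
    )
    rows = []
    for rid, grp in merged.groupby("response_id", sort=True):
        label = grp["label"].iloc[0]
        onset = grp["onset"].iloc[0]
        if label == "non-stepping":
            win = grp[(grp["time"] >= onset - 1e-9) & (grp["time"] <= onset + 4.0 + 1e-9)]
            rows.append(win)
        else:
            t_pred = grp[f"t_{timestep}"].iloc[0]
            idx = (grp["time"] - t_pred).abs()
            if idx.min() > 0.005 + 1e-9:
                raise ValueError(f"prediction time step {t_pred} outside record of {rid}")
            rows.append(grp.loc[[idx.idxmin()]])
    out = pd.concat(rows, ignore_index=True)
    out["y"] = (out["label"] == "stepping").astype(int)
    return out


def evaluation_windows(
    feature_table: pd.DataFrame,
    labels: pd.DataFrame,
    timestep: str,
    feature_names: list[str],
) -> dict[str, tuple[np.ndarray, int]]:
    """Per-response evaluation windows for one prediction time step.

    Stepping responses are scored on all observations from onset to their
    prediction time step; non-stepping responses on onset to onset + 4 s.
    Returns ``{response_id: (X_window, y)}``.
    """
    if timestep not in TIMESTEP_KEYS:
        raise ValueError(f"unknown prediction time step {timestep!r}")
    merged = feature_table.merge(
        labels[["response_id", "label", "onset", f"t_{timestep}"]], on="response_id"
    )
    windows: dict[str, tuple[np.ndarray, int]] = {}
    for rid, grp in merged.groupby("response_id", sort=True):
        label = grp["label"].iloc[0]
        onset = grp["onset"].iloc[0]
        if label == "non-stepping":
            end = onset + 4.0
        else:
            end = grp[f"t_{timestep}"].iloc[0]
        win = grp[(grp["time"] >= onset - 1e-9) & (grp["time"] <= end + 1e-9)]
        if win.empty:
            raise ValueError(f"empty observation window for response {rid}")
        windows[rid] = (win[feature_names].to_numpy(), int(label == "stepping"))
    return windows
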