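"""The 15-feature set: extraction, per-subject normalization, and
training-scope standardization.

Positional features are normalized per subject (CoM by the baseline CoM
height, CoP by foot length / stance width, joint centres by body height;
angular momentum by ``M h_com^2``); accelerations and joint angles are
left in physical units.  All features are subsequently standardized to
zero mean / unit variance using statistics of the *training split only*
(``x' = (x - mean)/sd``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .response import ProcessedResponse

__all__ = [
    "FEATURE_NAMES",
    "COP_FEATURES",
    "KINEMATIC_FEATURES",
    "FeatureStats",
    "feature_table",
    "extract_features",
    "fit_stats",
    "standardize",
]

FEATURE_NAMES = (
    "x_com",
    "xd_com",
    "xdd_com",
    "k_com",
    "x_cop",
    "xd_cop",
    "xdd_cop",
    "y_cop",
    "yd_cop",
    "ydd_cop",
    "theta_hip",
    "theta_knee",
    "x_cjc",
    "x_hip",
    "x_knee",
)

#: The six CoP-derived columns dismissed for the kinematics-only set.
COP_FEATURES = ("x_cop", "xd_cop", "xdd_cop", "y_cop", "yd_cop", "ydd_cop")

#: Kinematics feature set: the full set minus every CoP-derived column.
KINEMATIC_FEATURES = tuple(f for f in FEATURE_NAMES if f not in COP_FEATURES)


def feature_table(response: ProcessedResponse) -> pd.DataFrame:
    """Per-sample normalized feature rows for one processed response.

    Rows cover the analysis window (onset to onset + 4 s for
    non-stepping responses; onset to toe-off for stepping responses,
    when the true toe-off time is known).
    """
    s = response.subject
    ch = response.channels
    t = response.t

    end = response.onset + 4.0
    if response.label == "stepping" and response.truth.get("t_TO") is not None:
        end = min(end, float(response.truth["t_TO"]) + 0.02)
    # include the 2 s baseline so pre-perturbation instants can be inspected;
    # observation-set builders select from onset onward
    mask = (t >= response.onset - 2.0 - 1e-9) & (t <= end + 1e-9)

    table = pd.DataFrame(
        {
            "response_id": response.response_id,
            "subject_id": response.subject_id,
            "time": t[mask],
            "x_com": ch["x_com"][mask] / s.com_height,
            "xd_com": ch["xd_com"][mask] / s.com_height,
            "xdd_com": ch["xdd_com"][mask],
            "k_com": ch["k_com"][mask] / (s.mass * s.com_height**2),
            "x_cop": ch["cop_x"][mask] / s.foot_length,
            "xd_cop": ch["cop_xd"][mask] / s.foot_length,
            "xdd_cop": ch["cop_xdd"][mask],
            "y_cop": ch["cop_y"][mask] / s.stance_width,
            "yd_cop": ch["cop_yd"][mask] / s.stance_width,
            "ydd_cop": ch["cop_ydd"][mask],
            "theta_hip": ch["theta_hip"][mask],
            "theta_knee": ch["theta_knee"][mask],
            "x_cjc": ch["x_cjc"][mask] / s.height,
            "x_hip": ch["x_hip"][mask] / s.height,
            "x_knee": ch["x_knee"][mask] / s.height,
        }
    )
    return table.dropna(subset=list(FEATURE_NAMES)).reset_index(drop=True)


def extract_features(response: ProcessedResponse, time: float) -> pd.Series:
    """The 15-entry normalized feature vector at one time instant."""
    table = feature_table(response)
    idx = (table["time"] - time).abs()
    if idx.min() > 0.005 + 1e-9:
        raise ValueError(f"time {time} s outside the feature record")
    return table.loc[idx.idxmin(), list(FEATURE_NAMES)]


@dataclass
class FeatureStats:
    """Per-feature mean and standard deviation (training-set scope)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        zero = self.sd[self.sd <= 0]
        if len(zero):
            raise ValueError(f"degenerate (zero-variance) feature(s): {list(zero.index)}")


def fit_stats(table: pd.DataFrame, feature_names=FEATURE_NAMES) -> FeatureStats:
    """Mean/sd of each feature column, to be fitted on the training split."""
    cols = table[list(feature_names)]
    return FeatureStats(mean=cols.mean(), sd=cols.std(ddof=1))


def standardize(table: pd.DataFrame, stats: FeatureStats) -> pd.DataFrame:
    """Apply ``x' = (x - mean)/sd`` with training-split statistics."""
    out = table.copy()
    names = list(stats.mean.index)
    missing = set(names) - set(out.columns)
    if missing:
        raise ValueError(f"feature columns missing from table: {sorted(missing)}")
    out[names] = (out[names] - stats.mean) / stats.sd
    return out
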