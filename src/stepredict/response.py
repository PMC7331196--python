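"""Containers for raw and processed balance responses, plus CSV round-trip.

A :class:`BalanceResponse` holds one perturbation trial: per-foot force
plate channels at 1000 Hz, kinematic channels at 100 Hz, the perturbation
force trace and onset, and the generator's ground-truth metadata (label,
event times) when the trial is synthetic.

On disk a cohort is one directory::

    cohort/
      subjects.csv        anthropometry table
      manifest.json       generator config echo, seed, per-response metadata
      responses/<id>.csv  long format: time, channel, value

Force channels carry a ``f1k:`` prefix in the long format so the two
sample rates can be separated on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import (
    SubjectAnthropometry,
    subjects_from_frame,
    subjects_to_frame,
)

__all__ = ["BalanceResponse", "ProcessedResponse", "write_cohort", "read_cohort"]

FORCE_RATE = 1000.0
KIN_RATE = 100.0

FORCE_CHANNELS = ("fz_l", "fz_r", "mx_l", "mx_r", "my_l", "my_r", "pert_force")
KIN_CHANNELS = (
    "x_com",
    "xd_com",
    "xdd_com",
    "k_com",
    "x_cjc",
    "x_hip",
    "x_knee",
    "x_ankle_l",
    "x_ankle_r",
    "theta_hip",
    "theta_knee",
)


@dataclass
class BalanceResponse:
    """One raw perturbation trial (synthetic or loaded from disk)."""

    subject_id: str
    response_id: str
    onset: float  # perturbation onset time (s) on the common clock
    t_force: np.ndarray  # 1000 Hz timestamps
    force: dict[str, np.ndarray]  # per-foot F_z, M_x, M_y + perturbation trace
    t_kin: np.ndarray  # 100 Hz timestamps
    kin: dict[str, np.ndarray]
    label: str  # ground-truth {"stepping", "non-stepping"}
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_f, n_k = len(self.t_force), len(self.t_kin)
        for name, arr in self.force.items():
            if len(arr) != n_f:
                raise ValueError(f"force channel {name} length mismatch")
        for name, arr in self.kin.items():
            if len(arr) != n_k:
                raise ValueError(f"kinematic channel {name} length mismatch")

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (time, channel, value) table for CSV export."""
        parts = []
        for name in sorted(self.force):
            parts.append(
                pd.DataFrame(
                    {"time": self.t_force, "channel": f"f1k:{name}", "value": self.force[name]}
                )
            )
        for name in sorted(self.kin):
            parts.append(
                pd.DataFrame({"time": self.t_kin, "channel": name, "value": self.kin[name]})
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_long_frame(
        cls,
        frame: pd.DataFrame,
        *,
        subject_id: str,
        response_id: str,
        onset: float,
        label: str,
        truth: dict | None = None,
    ) -> "BalanceResponse":
        force: dict[str, np.ndarray] = {}
        kin: dict[str, np.ndarray] = {}
        t_force = t_kin = None
        for channel, grp in frame.groupby("channel", sort=False):
            values = grp["value"].to_numpy()
            times = grp["time"].to_numpy()
            if str(channel).startswith("f1k:"):
                force[str(channel)[4:]] = values
                t_force = times
            else:
                kin[str(channel)] = values
                t_kin = times
        if t_force is None or t_kin is None:
            raise ValueError("long frame is missing force or kinematic channels")
        return cls(
            subject_id=subject_id,
            response_id=response_id,
            onset=onset,
            t_force=t_force,
            force=force,
            t_kin=t_kin,
            kin=kin,
            label=label,
            truth=dict(truth or {}),
        )


@dataclass
class ProcessedResponse:
    """Filtered, resampled, synchronized channels on the 100 Hz clock.

    All channels live on the common ``t`` grid: filtered kinematics with
    derivatives, resampled+filtered per-foot vertical forces, and the net
    centre of pressure with derivatives.  Positions are expressed relative
    to the mean ankle position over the 2 s pre-perturbation baseline.
    """

    subject_id: str
    response_id: str
    onset: float
    subject: SubjectAnthropometry
    t: np.ndarray
    channels: dict[str, np.ndarray]
    label: str
    truth: dict = field(default_factory=dict)

    def sample_index(self, time: float) -> int:
        """Index of the grid sample nearest to ``time`` (within half a step)."""
        if time < self.t[0] - 5e-3 or time > self.t[-1] + 5e-3:
            raise ValueError(f"time {time} s outside recorded window")
        return int(np.argmin(np.abs(self.t - time)))


def _truth_jsonable(truth: dict) -> dict:
    out = {}
    for key, value in truth.items():
        if isinstance(value, np.ndarray):
            continue  # trajectories are not part of the manifest
        if isinstance(value, (np.floating, np.integer)):
            value = value.item()
        out[key] = value
    return out


def write_cohort(
    responses: list[BalanceResponse],
    subjects: list[SubjectAnthropometry],
    directory: str | Path,
    *,
    config_echo: dict | None = None,
) -> Path:
    """Write a cohort directory (subjects.csv, manifest.json, responses/)."""
    directory = Path(directory)
    (directory / "responses").mkdir(parents=True, exist_ok=True)
    subjects_to_frame(subjects).to_csv(directory / "subjects.csv", index=False)
    meta = {}
    for resp in responses:
        resp.to_long_frame().to_csv(
            directory / "responses" / f"{resp.response_id}.csv", index=False
        )
        meta[resp.response_id] = {
            "subject_id": resp.subject_id,
            "onset": float(resp.onset),
            "label": resp.label,
            "truth": _truth_jsonable(resp.truth),
        }
    manifest = {"config": config_echo or {}, "responses": meta}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return directory


def read_cohort(directory: str | Path) -> tuple[list[BalanceResponse], list[SubjectAnthropometry]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    subjects = subjects_from_frame(pd.read_csv(directory / "subjects.csv"))
    manifest = json.loads((directory / "manifest.json").read_text())
    responses = []
    for response_id, meta in sorted(manifest["responses"].items()):
        frame = pd.read_csv(directory / "responses" / f"{response_id}.csv")
        responses.append(
            BalanceResponse.from_long_frame(
                frame,
                subject_id=meta["subject_id"],
                response_id=response_id,
                onset=meta["onset"],
                label=meta["label"],
                truth=meta.get("truth", {}),
            )
        )
    return responses, subjects
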