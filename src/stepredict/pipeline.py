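"""End-to-end orchestration: simulate -> preprocess -> label -> features ->
train/evaluate classifiers and conventional predictors -> report tables.

A :class:`PipelineConfig` is fully serializable (YAML); a run writes its
manifest next to the metric tables so the run can be reproduced
byte-identically.  All randomness flows from the generator seed and the
split seed recorded in the config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conventional as conv
from .anthropometry import SubjectAnthropometry
from .classify import (
    ClassifierSpec,
    confusion_metrics,
    evaluate_windows,
    sweep_threshold,
    train,
    window_max_scores,
)
from .features import (
    FEATURE_NAMES,
    KINEMATIC_FEATURES,
    feature_table,
    fit_stats,
    standardize,
)
from .labeling import (
    TIMESTEP_KEYS,
    build_observation_set,
    detect_step,
    evaluation_windows,
    prediction_timesteps,
    screen_response,
    split_dataset,
)
from .preprocess import FilterSpec, process_response
from .response import ProcessedResponse
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "LabeledCohort", "prepare_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable description of one full analysis run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    classifiers: list[dict] = field(
        default_factory=lambda: [
            {"kind": "LDA"},
            {"kind": "QDA"},
            {"kind": "LSVM"},
            {"kind": "NN", "hidden_neurons": 8},
        ]
    )
    timesteps: list[str] = field(default_factory=lambda: list(TIMESTEP_KEYS))
    feature_set: str = "full"  # "full" or "kinematics"
    split_seed: int = 7
    motion_cutoff_hz: float = 5.0
    force_cutoff_hz: float = 8.0

    def __post_init__(self) -> None:
        if self.feature_set not in ("full", "kinematics"):
            raise ValueError("feature_set must be 'full' or 'kinematics'")
        for key in self.timesteps:
            if key not in TIMESTEP_KEYS:
                raise ValueError(f"unknown prediction time step {key!r}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES if self.feature_set == "full" else KINEMATIC_FEATURES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["generator"] = GeneratorConfig.from_dict(d.get("generator", {}))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LabeledCohort:
    """Processed, screened, labeled and split cohort with feature tables."""

    processed: dict[str, ProcessedResponse]
    subjects: list[SubjectAnthropometry]
    labels: pd.DataFrame  # response_id, subject_id, label, t_SLU, t_TO, t_<key>..., split
    features: pd.DataFrame  # standardized feature table with split tags
    stats_mean: pd.Series
    stats_sd: pd.Series
    dismissed: pd.DataFrame


def prepare_cohort(config: PipelineConfig) -> LabeledCohort:
    """Generate, preprocess, label, screen, split and featurize a cohort."""
    responses, subjects = generate_cohort(config.generator)
    by_id = {s.subject_id: s for s in subjects}
    motion = FilterSpec(cutoff_hz=config.motion_cutoff_hz)
    force = FilterSpec(cutoff_hz=config.force_cutoff_hz)

    processed: dict[str, ProcessedResponse] = {}
    rows, dismissed = [], []
    for resp in responses:
        proc = process_response(resp, by_id[resp.subject_id], motion, force)
        label, events = detect_step(proc)
        if label == "excluded":
            dismissed.append({"response_id": resp.response_id, "reason": "excluded"})
            continue
        verdict, reason = screen_response(proc, label == "stepping")
        if verdict == "dismiss":
            dismissed.append({"response_id": resp.response_id, "reason": reason})
            continue
        row = {
            "response_id": resp.response_id,
            "subject_id": resp.subject_id,
            "label": label,
            "onset": proc.onset,
            "t_SLU": events.t_SLU if events else np.nan,
            "t_TO": events.t_TO if events else np.nan,
        }
        if events:
            proc.truth["t_TO_detected"] = events.t_TO
            for key, val in prediction_timesteps(events.t_SLU, events.t_TO).items():
                row[f"t_{key}"] = val
        processed[resp.response_id] = proc
        rows.append(row)

    labels = pd.DataFrame(rows)
    if labels.empty or labels["label"].nunique() < 2:
        raise RuntimeError("cohort does not contain both classes after screening")
    split = split_dataset(labels, config.split_seed)
    labels["split"] = labels["response_id"].map(split)

    tables = []
    for rid, proc in processed.items():
        tbl = feature_table(proc)
        tables.append(tbl)
    features = pd.concat(tables, ignore_index=True)
    features = features.merge(labels[["response_id", "split"]], on="response_id")

    train_mask = features["split"] == "train"
    stats = fit_stats(features.loc[train_mask], FEATURE_NAMES)
    features = standardize(features, stats)

    return LabeledCohort(
        processed=processed,
        subjects=subjects,
        labels=labels,
        features=features,
        stats_mean=stats.mean,
        stats_sd=stats.sd,
        dismissed=pd.DataFrame(dismissed, columns=["response_id", "reason"]),
    )


def _split_frames(cohort: LabeledCohort):
    lab = cohort.labels
    feats = cohort.features
    out = {}
    for split in ("train", "validation", "test"):
        ids = set(lab.loc[lab["split"] == split, "response_id"])
        out[split] = (
            feats[feats["response_id"].isin(ids)],
            lab[lab["response_id"].isin(ids)],
        )
    return out


def evaluate_classifiers(config: PipelineConfig, cohort: LabeledCohort) -> pd.DataFrame:
    """Train every classifier family at every prediction time step.

    For each (family, time step): fit on the training observation set,
    sweep the score threshold on the validation responses, then apply the
    chosen threshold to the test responses.  Returns one row per
    (method, time step, split).
    """
    names = list(config.feature_names)
    frames = _split_frames(cohort)
    rows = []
    for spec_dict in config.classifiers:
        spec = ClassifierSpec(**spec_dict)
        label = spec.kind if spec.kind != "NN" else f"NN-{spec.hidden_neurons}"
        for ts in config.timesteps:
            obs = build_observation_set(frames["train"][0], frames["train"][1], ts)
            model = train(spec, obs[names].to_numpy(), obs["y"].to_numpy())
            val_windows = evaluation_windows(frames["validation"][0], frames["validation"][1], ts, names)
            _, max_scores, y_val = window_max_scores(model, val_windows)
            threshold, val_metrics = sweep_threshold(max_scores, y_val)
            rows.append(_metrics_row(label, ts, "validation", val_metrics, threshold))
            test_windows = evaluation_windows(frames["test"][0], frames["test"][1], ts, names)
            test_metrics = evaluate_windows(model, test_windows, threshold)
            rows.append(_metrics_row(label, ts, "test", test_metrics, threshold))
    return pd.DataFrame(rows)


def _metrics_row(method, timestep, split, metrics, threshold):
    return {
        "method": method,
        "timestep": timestep,
        "split": split,
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "tp": metrics.tp,
        "fn": metrics.fn,
        "tn": metrics.tn,
        "fp": metrics.fp,
        "threshold": threshold,
    }


def _state_windows(cohort: LabeledCohort, labels: pd.DataFrame, timestep: str):
    """Physical-unit CoM state windows (x, xd) per response."""
    out = {}
    for _, row in labels.iterrows():
        proc = cohort.processed[row["response_id"]]
        t = proc.t
        end = row["onset"] + 4.0
        if row["label"] == "stepping":
            end = row[f"t_{timestep}"]
        mask = (t >= row["onset"] - 1e-9) & (t <= end + 1e-9)
        out[row["response_id"]] = (
            proc.channels["x_com"][mask],
            proc.channels["xd_com"][mask],
            proc.subject,
            int(row["label"] == "stepping"),
        )
    return out


def evaluate_conventional(config: PipelineConfig, cohort: LabeledCohort) -> pd.DataFrame:
    """Stability boundary, XCoM and TTB baselines at every time step.

    A response is predicted stepping when any sample in its observation
    window triggers the predictor.  The XCoM BoS scale is chosen on the
    validation set from a fixed grid; the TTB threshold is optimized on
    the training + validation responses.
    """
    frames = _split_frames(cohort)
    rows = []
    for ts in config.timesteps:
        windows = {
            split: _state_windows(cohort, frames[split][1], ts)
            for split in ("train", "validation", "test")
        }

        # --- stability boundary (no free parameter) --------------------
        for split in ("validation", "test"):
            preds, labs = [], []
            for x, v, subj, y in windows[split].values():
                trig = conv.stability_boundary_predict(x, v, subj.height, subj.x_heel, subj.x_toe)
                preds.append(bool(np.any(trig)))
                labs.append(y)
            rows.append(_metrics_row("SB", ts, split, confusion_metrics(np.array(preds), np.array(labs)), np.nan))

        # --- XCoM with BoS scale chosen on validation ------------------
        def xcom_preds(split, scale):
            preds, labs = [], []
            params = conv.ConventionalParams(bos_scale=scale)
            for x, v, subj, y in windows[split].values():
                trig = conv.xcom_predict(x, v, subj.x_heel, subj.foot_length, params, subj.com_height)
                preds.append(bool(np.any(trig)))
                labs.append(y)
            return np.array(preds), np.array(labs)

        best_scale, best_key = None, None
        for scale in conv.BOS_SCALE_GRID:
            preds, labs = xcom_preds("validation", scale)
            m = confusion_metrics(preds, labs)
            key = (m.accuracy, m.sensitivity + m.specificity)
            if best_key is None or key > best_key:
                best_key, best_scale = key, scale
        for split in ("validation", "test"):
            preds, labs = xcom_preds(split, best_scale)
            rows.append(_metrics_row("XCoM", ts, split, confusion_metrics(preds, labs), best_scale))

        # --- TTB with threshold optimized on train + validation --------
        def min_taus(split):
            taus, labs = [], []
            for x, v, subj, y in windows[split].values():
                taus.append(float(np.min(conv.ttb(x, v, subj.x_toe))))
                labs.append(y)
            return np.array(taus), np.array(labs)

        tau_tv = [min_taus("train"), min_taus("validation")]
        tau_fit = np.concatenate([t for t, _ in tau_tv])
        lab_fit = np.concatenate([l for _, l in tau_tv])
        thr, _ = conv.optimize_ttb_threshold(tau_fit, lab_fit)
        for split in ("validation", "test"):
            taus, labs = min_taus(split)
            rows.append(_metrics_row("TTB", ts, split, confusion_metrics(taus < thr, labs), thr))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write metric tables + manifest.

    Writes ``labels.csv``, ``splits.csv``, ``features.csv``,
    ``comparison.csv`` (classifiers + conventional methods, validation
    and test) and ``manifest.yaml`` into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = prepare_cohort(config)

    comparison = pd.concat(
        [evaluate_classifiers(config, cohort), evaluate_conventional(config, cohort)],
        ignore_index=True,
    )

    label_cols = ["response_id", "subject_id", "label", "t_SLU", "t_TO"]
    cohort.labels[label_cols].to_csv(outdir / "labels.csv", index=False)
    cohort.labels[["response_id", "split"]].to_csv(outdir / "splits.csv", index=False)
    cohort.features.to_csv(outdir / "features.csv", index=False)
    comparison.to_csv(outdir / "comparison.csv", index=False)
    cohort.dismissed.to_csv(outdir / "dismissed.csv", index=False)
    config.save(outdir / "manifest.yaml")
    return {
        "comparison": comparison,
        "labels": cohort.labels,
        "features": cohort.features,
        "dismissed": cohort.dismissed,
    }
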