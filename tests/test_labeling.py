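"""Step detection, SLU search, prediction time steps, screening, splits
and observation-set construction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepredict.labeling import (
    TIMESTEP_KEYS,
    build_observation_set,
    detect_slu,
    detect_step,
    prediction_timesteps,
    screen_response,
    split_dataset,
)
from stepredict.response import ProcessedResponse


def _make_processed(subject, channels, onset=2.0, fs=100.0, label="non-stepping", truth=None):
    n = len(next(iter(channels.values())))
    return ProcessedResponse(
        subject_id=subject.subject_id,
        response_id="RTEST",
        onset=onset,
        subject=subject,
        t=np.arange(n) / fs,
        channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
        label=label,
        truth=truth or {},
    )


def _quiet_channels(n, weight=735.0):
    return {
        "fz_l": np.full(n, weight / 2),
        "fz_r": np.full(n, weight / 2),
        "x_com": np.zeros(n),
        "xd_com": np.zeros(n),
        "x_ankle_l": np.zeros(n),
        "x_ankle_r": np.zeros(n),
        "cop_x": np.zeros(n),
    }


class TestDetectStep:
    def _stepping_channels(self, n, t_drop_idx, step_length=0.3, reload_idx=None):
        ch = _quiet_channels(n)
        fz = ch["fz_l"].copy()
        fz[t_drop_idx:] = 15.0
        if reload_idx is not None:
            fz[reload_idx:] = 367.5
        ch["fz_l"] = fz
        ankle = np.zeros(n)
        ankle[t_drop_idx:] = step_length
        ch["x_ankle_l"] = ankle
        return ch

    def test_valid_step_detected(self, subject):
        n = 500  # 5 s at 100 Hz, onset at 2 s
        ch = self._stepping_channels(n, t_drop_idx=280)
        label, events = detect_step(_make_processed(subject, ch))
        assert label == "stepping"
        assert events.stepping_foot == "l"
        assert events.step_length == pytest.approx(0.3, abs=1e-9)

    def test_late_step_excluded(self, subject):
        n = 600
        ch = self._stepping_channels(n, t_drop_idx=460)  # 2.6 s after onset
        label, events = detect_step(_make_processed(subject, ch))
        assert label == "excluded" and events is None

    def test_short_step_excluded(self, subject):
        n = 500
        ch = self._stepping_channels(n, t_drop_idx=280, step_length=0.04)
        label, _ = detect_step(_make_processed(subject, ch))
        assert label == "excluded"  # 0.04 m < 20% of 0.27 m foot

    def test_both_feet_loaded_is_non_stepping(self, subject):
        label, events = detect_step(_make_processed(subject, _quiet_channels(400)))
        assert label == "non-stepping" and events is None

    def test_missing_channel_rejected(self, subject):
        ch = _quiet_channels(300)
        del ch["fz_r"]
        with pytest.raises(ValueError):
            detect_step(_make_processed(subject, ch))


class TestDetectSlu:
    def test_single_peak_then_fall(self, subject):
        n = 400
        ch = _quiet_channels(n)
        fz = np.full(n, 367.5)
        fz[200:250] = np.linspace(367.5, 400.0, 50)  # load up, peak at i=249
        fz[250:300] = np.linspace(400.0, 0.0, 51)[1:]  # steep monotone fall
        fz[300:] = 0.0
        ch["fz_l"] = fz
        proc = _make_processed(subject, ch)
        t_slu = detect_slu(proc, t_to=3.0, foot="l")
        assert t_slu == pytest.approx(2.49, abs=1e-9)

    def test_generator_truth_recovered(self, noiseless_cohort):
        _, responses, _, processed = noiseless_cohort
        errs = []
        for raw, proc in zip(responses, processed):
            label, events = detect_step(proc)
            if label == "stepping":
                errs.append(abs(events.t_SLU - raw.truth["t_SLU"]))
        assert len(errs) > 30
        assert max(errs) <= 0.02

    def test_monotone_from_start_warns(self, subject):
        n = 300
        ch = _quiet_channels(n)
        ch["fz_l"] = np.linspace(400.0, 0.0, n)
        proc = _make_processed(subject, ch)
        with pytest.warns(UserWarning):
            t_slu = detect_slu(proc, t_to=proc.t[-1], foot="l")
        assert t_slu == proc.t[0]


class TestPredictionTimesteps:
    def test_equal_spacing_example(self):
        steps = prediction_timesteps(0.40, 0.56)
        expected = [0.32, 0.36, 0.40, 0.44, 0.48, 0.52, 0.56]
        assert [steps[k] for k in TIMESTEP_KEYS] == pytest.approx(expected, abs=1e-12)

    def test_mean_interval_layout_relative_to_toe_off(self):
        # SLU 0.16 s before TO: within-interval steps land at -0.12, -0.08,
        # -0.04, 0 relative to TO
        steps = prediction_timesteps(1.00 - 0.16, 1.00)
        rel = [steps[k] - 1.00 for k in ("TO-3", "TO-2", "TO-1", "TO")]
        assert rel == pytest.approx([-0.12, -0.08, -0.04, 0.0], abs=1e-12)

    def test_minimal_spacing_still_distinct(self):
        steps = prediction_timesteps(0.52, 0.56)
        values = [steps[k] for k in TIMESTEP_KEYS]
        assert len(set(values)) == 7
        np.testing.assert_allclose(np.diff(values), 0.01, atol=1e-12)

    def test_spacing_equal_within_one_sample(self, noiseless_cohort):
        _, _, _, processed = noiseless_cohort
        checked = 0
        for proc in processed:
            label, ev = detect_step(proc)
            if label != "stepping":
                continue
            steps = prediction_timesteps(ev.t_SLU, ev.t_TO)
            diffs = np.diff([steps[k] for k in TIMESTEP_KEYS])
            assert np.max(diffs) - np.min(diffs) <= 0.01 + 1e-12
            checked += 1
        assert checked > 30

    def test_reversed_events_rejected(self):
        with pytest.raises(ValueError):
            prediction_timesteps(0.5, 0.4)


class TestScreenResponse:
    def test_forward_lean_dismissed(self, subject):
        ch = _quiet_channels(500)
        ch["x_com"] = np.full(500, 0.04)
        verdict, reason = screen_response(_make_processed(subject, ch), is_step=False)
        assert (verdict, reason) == ("dismiss", "lean")

    def test_quiet_balanced_trial_kept(self, subject):
        verdict, reason = screen_response(
            _make_processed(subject, _quiet_channels(500)), is_step=False
        )
        assert (verdict, reason) == ("keep", None)

    def test_uneven_load_dismissed(self, subject):
        ch = _quiet_channels(500)
        ch["fz_l"] = np.full(500, 0.70 * 735.0)
        ch["fz_r"] = np.full(500, 0.30 * 735.0)
        verdict, reason = screen_response(_make_processed(subject, ch), is_step=False)
        assert (verdict, reason) == ("dismiss", "uneven-load")

    def test_sustained_forward_cop_dismissed(self, subject):
        ch = _quiet_channels(700)
        cop = np.zeros(700)
        cop[210:290] = subject.x_toe - 0.01  # 0.8 s in the front 20% of the foot
        ch["cop_x"] = cop
        verdict, reason = screen_response(_make_processed(subject, ch), is_step=False)
        assert (verdict, reason) == ("dismiss", "heel-lift")


class TestSplitDataset:
    def _labels(self, n_step=20, n_non=40):
        rows = [
            {"response_id": f"R{i:03d}", "subject_id": "S01",
             "label": "stepping" if i < n_step else "non-stepping"}
            for i in range(n_step + n_non)
        ]
        return pd.DataFrame(rows)

    def test_exact_fractions(self):
        labels = self._labels()
        split = split_dataset(labels, seed=0)
        merged = labels.assign(split=labels["response_id"].map(split))
        counts = merged.groupby(["label", "split"]).size().unstack()
        assert counts.loc["stepping", "test"] == 3
        assert counts.loc["stepping", "train"] == 12
        assert counts.loc["stepping", "validation"] == 5
        assert counts.loc["non-stepping", "test"] == 6
        assert counts.loc["non-stepping", "train"] == 24
        assert counts.loc["non-stepping", "validation"] == 10

    def test_deterministic_under_seed(self):
        labels = self._labels()
        a = split_dataset(labels, seed=5)
        b = split_dataset(labels, seed=5)
        assert (a == b).all()
        c = split_dataset(labels, seed=6)
        assert (a != c).any()

    def test_partition_properties_over_many_cohorts(self, rng):
        # splits are disjoint, cover everything, and conserve per-subject
        # class ratios up to one response
        for trial in range(100):
            rows = []
            rid = 0
            for subj in ("S01", "S02"):
                n_step = int(rng.integers(4, 15))
                n_non = int(rng.integers(4, 25))
                for i in range(n_step + n_non):
                    rows.append({
                        "response_id": f"R{rid:04d}", "subject_id": subj,
                        "label": "stepping" if i < n_step else "non-stepping",
                    })
                    rid += 1
            labels = pd.DataFrame(rows)
            split = split_dataset(labels, seed=trial)
            assert split.notna().all()
            merged = labels.assign(split=labels["response_id"].map(split))
            for (subj, _), grp in merged.groupby(["subject_id", "label"]):
                n = len(grp)
                n_test = (grp["split"] == "test").sum()
                n_train = (grp["split"] == "train").sum()
                assert abs(n_test - 0.15 * n) <= 0.5 + 1e-9
                assert abs(n_train - 0.70 * (n - n_test)) <= 0.5 + 1e-9


class TestObservationSets:
    def _feature_table(self, rid, times):
        return pd.DataFrame({
            "response_id": rid,
            "time": times,
            "f1": np.linspace(0, 1, len(times)),
        })

    def _labels(self, rid, label, onset=2.0, t_slu=2.4):
        row = {"response_id": rid, "label": label, "onset": onset, "t_SLU-2": t_slu}
        return pd.DataFrame([row])

    def test_non_stepping_contributes_401_observations(self):
        times = np.round(np.arange(0.0, 6.5, 0.01), 10)
        table = self._feature_table("R1", times)
        obs = build_observation_set(table, self._labels("R1", "non-stepping"), "SLU-2")
        assert len(obs) == 401
        assert (obs["y"] == 0).all()

    def test_stepping_contributes_single_observation(self):
        times = np.round(np.arange(2.0, 3.0, 0.01), 10)
        table = self._feature_table("R2", times)
        obs = build_observation_set(table, self._labels("R2", "stepping"), "SLU-2")
        assert len(obs) == 1
        assert obs["time"].iloc[0] == pytest.approx(2.4)
        assert (obs["y"] == 1).all()

    def test_out_of_record_timestep_rejected(self):
        times = np.round(np.arange(2.0, 2.2, 0.01), 10)
        table = self._feature_table("R3", times)
        with pytest.raises(ValueError):
            build_observation_set(table, self._labels("R3", "stepping", t_slu=2.8), "SLU-2")


def test_generator_labels_recovered_noiselessly(noiseless_cohort):
    _, responses, _, processed = noiseless_cohort
    agree = sum(detect_step(p)[0] == r.label for r, p in zip(responses, processed))
    assert agree / len(responses) >= 0.99
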