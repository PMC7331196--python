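"""Filtering, resampling, synchronization, CoP and CoM-kinematics checks."""

from __future__ import annotations

import numpy as np
import pytest

from stepredict.preprocess import (
    FORCE_FILTER,
    MOTION_FILTER,
    FilterSpec,
    com_kinematics,
    compute_cop,
    derivative,
    estimate_sync_delay,
    resample_to_100hz,
    zero_lag_lowpass,
)


class TestZeroLagLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(500, 3.7)
        out = zero_lag_lowpass(x, MOTION_FILTER, fs=100.0)
        np.testing.assert_allclose(out, x, atol=1e-10)

    @pytest.mark.parametrize(
        "freq,max_atten,max_phase_deg",
        [(1.0, 0.01, 0.5)],
    )
    def test_passband_sinusoid_preserved(self, freq, max_atten, max_phase_deg):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * freq * t)
        y = zero_lag_lowpass(x, MOTION_FILTER, fs=fs)
        core = slice(200, -200)  # ignore edge transients
        amp = np.max(np.abs(y[core]))
        assert amp > 1 - max_atten
        # zero-phase: cross-correlation peak at zero lag
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (len(x[core]) - 1)
        assert abs(lag) / fs * freq * 360 < max_phase_deg

    def test_stopband_sinusoid_removed(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 20.0 * t)
        y = zero_lag_lowpass(x, MOTION_FILTER, fs=fs)
        assert np.max(np.abs(y[100:-100])) < 0.01

    def test_symmetric_pulse_stays_symmetric(self):
        x = np.zeros(1001)
        x[400:601] = np.hanning(201)
        y = zero_lag_lowpass(x, FORCE_FILTER, fs=100.0)
        asym = np.max(np.abs(y - y[::-1])) / np.max(np.abs(y))
        assert asym < 1e-6

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            zero_lag_lowpass(np.zeros(10), MOTION_FILTER, fs=100.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            zero_lag_lowpass(np.zeros(100), FilterSpec(cutoff_hz=60.0), fs=100.0)


class TestResample:
    def test_constant(self):
        out = resample_to_100hz(np.full(1000, 700.0), fs_in=1000.0)
        assert len(out) == 100
        np.testing.assert_allclose(out, 700.0, rtol=1e-9)

    def test_linear_ramp_keeps_slope(self):
        t = np.arange(2000) / 1000.0
        out = resample_to_100hz(5.0 * t, fs_in=1000.0)
        slopes = np.diff(out) * 100.0
        np.testing.assert_allclose(slopes, 5.0, rtol=1e-6)

    def test_bandlimited_sinusoid_amplitude(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 2.0 * t)
        out = resample_to_100hz(x, fs_in=1000.0)
        t_out = np.arange(len(out)) / 100.0
        np.testing.assert_allclose(out[20:-20], np.sin(2 * np.pi * 2.0 * t_out)[20:-20], atol=0.01)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            resample_to_100hz(np.zeros(100), fs_in=250.0)


class TestSyncDelay:
    def _pattern(self, rng, n=400, fs=100.0):
        # pseudo-random steps every 0.1 s, sampled at fs
        steps = rng.normal(size=n // 10 + 1)
        return np.repeat(steps, 10)[:n]

    def test_identical_series_zero_delay(self, rng):
        x = self._pattern(rng)
        delay, ok = estimate_sync_delay(x, x, fs=100.0)
        assert delay == 0.0 and ok

    def test_constructed_shift_recovered(self, rng):
        x = self._pattern(rng, n=800)
        shift = 30  # 0.3 s at 100 Hz
        b = np.concatenate([np.zeros(shift), x])[: len(x)]
        delay, _ = estimate_sync_delay(x, b, fs=100.0)
        assert delay == pytest.approx(0.30, abs=1e-9)

    def test_noisy_shift_within_one_sample(self, rng):
        x = self._pattern(rng, n=800)
        shift = 30
        b = np.concatenate([np.zeros(shift), x])[: len(x)]
        b = b + rng.normal(0, np.std(x) / np.sqrt(10), len(b))  # SNR ~ 10
        delay, _ = estimate_sync_delay(x, b, fs=100.0)
        assert delay == pytest.approx(0.30, abs=0.01 + 1e-9)

    def test_ambiguous_peak_warns(self):
        x = np.sin(2 * np.pi * np.arange(200) / 20.0)  # periodic: many equal peaks
        with pytest.warns(UserWarning):
            _, ok = estimate_sync_delay(x, x, fs=100.0)
        assert not ok


class TestComputeCop:
    def test_direct_formula_values(self):
        trace = compute_cop(
            m_x=np.array([0.0, 35.0]),
            m_y=np.array([0.0, -70.0]),
            f_z=np.array([700.0, 700.0]),
        )
        np.testing.assert_allclose(trace.p_x, [0.0, 0.1])
        np.testing.assert_allclose(trace.p_y, [0.0, 0.05])

    def test_low_force_samples_masked(self):
        trace = compute_cop(np.array([1.0, 1.0]), np.array([1.0, 1.0]), np.array([700.0, 5.0]))
        assert trace.valid.tolist() == [True, False]
        assert np.isnan(trace.p_x[1]) and np.isnan(trace.p_y[1])


class TestComKinematics:
    def test_single_segment_equals_segment(self):
        x = np.linspace(0, 1, 200)
        out = com_kinematics(
            positions={"trunk": x},
            heights={"trunk": np.full(200, 1.0)},
            masses={"trunk": 40.0},
            inertias={},
            angles={},
            fs=100.0,
        )
        np.testing.assert_allclose(out["x_com"], x)

    def test_two_equal_masses_average(self):
        n = 100
        out = com_kinematics(
            positions={"a": np.zeros(n), "b": np.ones(n)},
            heights={"a": np.zeros(n), "b": np.zeros(n)},
            masses={"a": 10.0, "b": 10.0},
            inertias={},
            angles={},
            fs=100.0,
        )
        np.testing.assert_allclose(out["x_com"], 0.5)

    def test_rigid_rotation_angular_momentum(self):
        # two point masses on a rigid rod spinning at omega about its centroid
        fs, omega, r, m = 1000.0, 2.0, 0.5, 3.0
        t = np.arange(0, 2, 1 / fs)
        out = com_kinematics(
            positions={"a": r * np.cos(omega * t), "b": -r * np.cos(omega * t)},
            heights={"a": r * np.sin(omega * t), "b": -r * np.sin(omega * t)},
            masses={"a": m, "b": m},
            inertias={},
            angles={},
            fs=fs,
        )
        inertia = 2 * m * r**2
        # k = I * omega with the chosen sign convention (z x' - x z')
        np.testing.assert_allclose(out["k_com"][2:-2], -inertia * omega, rtol=1e-4)

    def test_mass_table_mismatch_rejected(self):
        n = 50
        with pytest.raises(ValueError):
            com_kinematics(
                positions={"a": np.zeros(n)},
                heights={"a": np.zeros(n)},
                masses={"a": 10.0},
                inertias={},
                angles={},
                fs=100.0,
                total_mass=70.0,
            )


class TestPipelineConsistency:
    def test_cop_recovery_on_noiseless_synthetic(self, noiseless_cohort):
        _, responses, _, _ = noiseless_cohort
        for raw in responses[:20]:
            trace = compute_cop(
                raw.force["mx_l"] + raw.force["mx_r"],
                raw.force["my_l"] + raw.force["my_r"],
                raw.force["fz_l"] + raw.force["fz_r"],
            )
            err = np.abs(trace.p_x[trace.valid] - raw.truth["cop_x"][trace.valid])
            assert np.max(err) < 1e-3  # < 1 mm

    def test_filtered_cop_close_to_truth_outside_transients(self, noiseless_cohort):
        _, responses, _, processed = noiseless_cohort
        for raw, proc in zip(responses[:20], processed[:20]):
            truth_cop = raw.truth["cop_x"][::10][: len(proc.t)]
            # compare away from the fast transients the 8 Hz filter smooths:
            # the pulse onset and, for steppers, the unloading/swing phase
            end = proc.onset + 1.5
            if raw.label == "stepping":
                end = min(end, raw.truth["t_SLU"] - 0.2)
            mask = (
                (proc.t >= proc.onset - 1.5)
                & (proc.t <= end)
                & ~((proc.t >= proc.onset - 0.1) & (proc.t <= proc.onset + 0.4))
                & (proc.channels["cop_valid"] > 0)
            )
            err = np.abs(proc.channels["cop_x"][mask] - truth_cop[mask])
            assert np.max(err) < 2e-3

    def test_velocity_integrates_back_to_position(self, noiseless_cohort):
        _, _, _, processed = noiseless_cohort
        for proc in processed[:20]:
            mask = (proc.t >= proc.onset - 2.0) & (proc.t <= proc.onset + 2.0)
            x = proc.channels["x_com"][mask]
            v = proc.channels["xd_com"][mask]
            recon = x[0] + np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0)]) / 100.0
            assert np.max(np.abs(recon - x)) < 1e-3  # < 1 mm over 4 s


def test_derivative_of_quadratic_is_linear():
    t = np.arange(0, 1, 0.01)
    d = derivative(t**2, fs=100.0)
    np.testing.assert_allclose(d[1:-1], 2 * t[1:-1], atol=1e-9)
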