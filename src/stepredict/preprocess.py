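"""Signal conditioning: zero-lag filtering, resampling, synchronization,
centre-of-pressure computation and CoM kinematics.

Force channels (1000 Hz) are resampled to the 100 Hz kinematic clock and
low-pass filtered at 8 Hz; kinematic channels are filtered at 5 Hz.  Both
use a 4th-order Butterworth applied forward and backward (zero phase), so
the effective magnitude response is 8th order.  The net centre of
pressure follows from the plate moments and vertical forces as
``p_x = -M_y / F_z`` and ``p_y = M_x / F_z``, masked invalid wherever the
vertical force is at or below a 20 N floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .anthropometry import SubjectAnthropometry
from .response import BalanceResponse, ProcessedResponse

__all__ = [
    "FilterSpec",
    "CopTrace",
    "zero_lag_lowpass",
    "resample_to_100hz",
    "estimate_sync_delay",
    "compute_cop",
    "com_kinematics",
    "derivative",
    "process_response",
    "FZ_FLOOR",
]

#: Vertical-force floor (N) below which the CoP quotient is ill-conditioned.
#: Reuses the step-detection force threshold.
FZ_FLOOR = 20.0


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter settings (4th-order zero-lag Butterworth)."""

    order: int = 4
    cutoff_hz: float = 5.0
    zero_lag: bool = True

    def validate(self, fs: float) -> None:
        if self.cutoff_hz <= 0 or self.cutoff_hz >= fs / 2:
            raise ValueError(f"cutoff {self.cutoff_hz} Hz must be below Nyquist of {fs} Hz")


MOTION_FILTER = FilterSpec(order=4, cutoff_hz=5.0)
FORCE_FILTER = FilterSpec(order=4, cutoff_hz=8.0)


@dataclass
class CopTrace:
    """Centre-of-pressure trace with a per-sample validity mask."""

    p_x: np.ndarray
    p_y: np.ndarray
    valid: np.ndarray


def zero_lag_lowpass(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Forward-backward Butterworth filter (zero phase shift).

    Edges are handled by reflective padding.  The series must be longer
    than three times the filter order for the padding to be defined.
    """
    series = np.asarray(series, dtype=float)
    spec.validate(fs)
    if series.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(series) <= 3 * spec.order:
        raise ValueError(f"series of length {len(series)} too short for order {spec.order}")
    b, a = signal.butter(spec.order, spec.cutoff_hz, fs=fs)
    if spec.zero_lag:
        return signal.filtfilt(b, a, series, padtype="even")
    return signal.lfilter(b, a, series)


def resample_to_100hz(series: np.ndarray, fs_in: float, fs_out: float = 100.0) -> np.ndarray:
    """Polyphase resampling from ``fs_in`` to the kinematic clock.

    The input rate must be an integer multiple of the output rate so that
    output timestamps align with existing input samples.
    """
    series = np.asarray(series, dtype=float)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"input rate {fs_in} is not an integer multiple of {fs_out} Hz")
    q = int(round(ratio))
    if q == 1:
        return series.copy()
    return signal.resample_poly(series, up=1, down=q, padtype="line")


def estimate_sync_delay(
    sync_a: np.ndarray, sync_b: np.ndarray, fs: float
) -> tuple[float, bool]:
    """Delay of ``sync_b`` relative to ``sync_a`` via cross-correlation.

    Both series should carry the same pseudo-random synchronization
    pattern.  Returns ``(delay_s, reliable)`` where ``delay_s`` is the lag
    maximizing the cross-correlation (positive when ``b`` lags ``a``) at
    one-sample resolution, and ``reliable`` is False when the correlation
    peak is not unambiguous (secondary peak within 5% of the maximum).
    """
    a = np.asarray(sync_a, dtype=float) - np.mean(sync_a)
    b = np.asarray(sync_b, dtype=float) - np.mean(sync_b)
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    best = int(np.argmax(corr))
    peak = corr[best]
    others = np.delete(corr, best)
    reliable = peak > 0 and (len(others) == 0 or np.max(others) < 0.95 * peak)
    if not reliable:
        import warnings

        warnings.warn("sync correlation peak is not unique; returning best lag", stacklevel=2)
    return lags[best] / fs, bool(reliable)


def compute_cop(m_x: np.ndarray, m_y: np.ndarray, f_z: np.ndarray, floor: float = FZ_FLOOR) -> CopTrace:
    """CoP from plate moments and vertical force: ``p_x = -M_y/F_z``,
    ``p_y = M_x/F_z``; samples with ``F_z <= floor`` are masked invalid."""
    m_x = np.asarray(m_x, dtype=float)
    m_y = np.asarray(m_y, dtype=float)
    f_z = np.asarray(f_z, dtype=float)
    valid = f_z > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        p_x = np.where(valid, -m_y / f_z, np.nan)
        p_y = np.where(valid, m_x / f_z, np.nan)
    return CopTrace(p_x=p_x, p_y=p_y, valid=valid)


def derivative(series: np.ndarray, fs: float) -> np.ndarray:
    """Central differences with one-sided differences at the edges."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("need at least three samples to differentiate")
    out = np.empty_like(series)
    out[1:-1] = (series[2:] - series[:-2]) * (fs / 2.0)
    out[0] = (series[1] - series[0]) * fs
    out[-1] = (series[-1] - series[-2]) * fs
    return out


def com_kinematics(
    positions: dict[str, np.ndarray],
    heights: dict[str, np.ndarray],
    masses: dict[str, float],
    inertias: dict[str, float],
    angles: dict[str, np.ndarray],
    fs: float,
    total_mass: float | None = None,
) -> dict[str, np.ndarray]:
    """Whole-body CoM kinematics from segment trajectories.

    ``positions``/``heights`` are per-segment x(t)/z(t) arrays, ``masses``
    per-segment masses (kg), ``inertias`` segment spin inertias about
    their own CoM (kg m^2), and ``angles`` the segment orientation
    trajectories (rad) used for the spin angular momentum.  If
    ``total_mass`` is given, the mass table must sum to it within 1%
    (feet are excluded from the reconstruction upstream).

    Returns x_com, xd_com, xdd_com and the angular momentum about the CoM
    (sum of orbital plus spin terms, about the mediolateral axis with
    forward rotation positive: ``k = sum m_i [(z_i - z_c)(xd_i - xd_c)
    - (x_i - x_c)(zd_i - zd_c)] + sum I_i thetad_i``).
    """
    names = sorted(masses)
    if set(positions) < set(names) or set(heights) < set(names):
        raise ValueError("positions/heights must cover every segment in the mass table")
    msum = sum(masses.values())
    if total_mass is not None and abs(msum - total_mass) > 0.01 * total_mass:
        raise ValueError(f"segment masses sum to {msum:.2f}, expected {total_mass:.2f} (within 1%)")

    x_c = sum(masses[s] * np.asarray(positions[s], dtype=float) for s in names) / msum
    z_c = sum(masses[s] * np.asarray(heights[s], dtype=float) for s in names) / msum
    xd_c = derivative(x_c, fs)
    zd_c = derivative(z_c, fs)
    xdd_c = derivative(xd_c, fs)

    k = np.zeros_like(x_c)
    for s in names:
        dx = np.asarray(positions[s], dtype=float) - x_c
        dz = np.asarray(heights[s], dtype=float) - z_c
        dvx = derivative(np.asarray(positions[s], dtype=float), fs) - xd_c
        dvz = derivative(np.asarray(heights[s], dtype=float), fs) - zd_c
        k += masses[s] * (dz * dvx - dx * dvz)
        if s in angles and s in inertias:
            k += inertias[s] * derivative(np.asarray(angles[s], dtype=float), fs)
    return {"x_com": x_c, "xd_com": xd_c, "xdd_com": xdd_c, "k_com": k}


def process_response(
    response: BalanceResponse,
    subject: SubjectAnthropometry,
    motion_filter: FilterSpec = MOTION_FILTER,
    force_filter: FilterSpec = FORCE_FILTER,
) -> ProcessedResponse:
    """Full conditioning of one raw response onto the 100 Hz clock.

    Force channels are resampled to 100 Hz and filtered at 8 Hz; motion
    channels are filtered at 5 Hz; the net CoP and its derivatives are
    computed; positions are re-expressed relative to the mean ankle
    position over the 2 s pre-perturbation baseline; CoM velocity and
    acceleration are recomputed as derivatives of the filtered position.
    """
    fs_kin = 1.0 / float(np.median(np.diff(response.t_kin)))
    fs_force = 1.0 / float(np.median(np.diff(response.t_force)))

    n_kin = len(response.t_kin)

    def cond_force(name: str) -> np.ndarray:
        res = resample_to_100hz(response.force[name], fs_force, fs_kin)[:n_kin]
        return zero_lag_lowpass(res, force_filter, fs_kin)

    fz_l = cond_force("fz_l")
    fz_r = cond_force("fz_r")
    mx = cond_force("mx_l") + cond_force("mx_r")
    my = cond_force("my_l") + cond_force("my_r")
    fz = fz_l + fz_r

    channels: dict[str, np.ndarray] = {"fz_l": fz_l, "fz_r": fz_r, "fz": fz}

    t = response.t_kin[:n_kin]
    baseline = (t >= response.onset - 2.0) & (t < response.onset)
    if not np.any(baseline):
        raise ValueError("no 2 s pre-perturbation baseline available")

    filt: dict[str, np.ndarray] = {}
    for name, arr in response.kin.items():
        filt[name] = zero_lag_lowpass(arr[:n_kin], motion_filter, fs_kin)

    ankle_ref = float(
        np.mean((filt["x_ankle_l"][baseline] + filt["x_ankle_r"][baseline]) / 2.0)
    )

    for name in ("x_com", "x_cjc", "x_hip", "x_knee", "x_ankle_l", "x_ankle_r"):
        channels[name] = filt[name] - ankle_ref
    for name in ("theta_hip", "theta_knee", "k_com"):
        channels[name] = filt[name]

    channels["xd_com"] = derivative(channels["x_com"], fs_kin)
    channels["xdd_com"] = derivative(channels["xd_com"], fs_kin)

    cop = compute_cop(mx, my, fz)
    channels["cop_x"] = cop.p_x - ankle_ref
    channels["cop_y"] = cop.p_y
    channels["cop_valid"] = cop.valid.astype(float)
    # derivatives on the valid span; invalid samples propagate as NaN
    px = np.where(cop.valid, channels["cop_x"], np.nan)
    py = np.where(cop.valid, channels["cop_y"], np.nan)
    channels["cop_xd"] = derivative(px, fs_kin)
    channels["cop_xdd"] = derivative(channels["cop_xd"], fs_kin)
    channels["cop_yd"] = derivative(py, fs_kin)
    channels["cop_ydd"] = derivative(channels["cop_yd"], fs_kin)

    return ProcessedResponse(
        subject_id=response.subject_id,
        response_id=response.response_id,
        onset=response.onset,
        subject=subject,
        t=t,
        channels=channels,
        label=response.label,
        truth=response.truth,
    )
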