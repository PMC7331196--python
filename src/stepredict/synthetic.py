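"""Seeded generator of synthetic perturbed-standing balance responses.

The generator emulates forward pelvis pushes during quiet stance: a
rectangular force pulse (default 0.2 s, magnitudes expressed as fractions
of body weight ``m*g``) applied to a sagittal single-link inverted
pendulum about the ankles, stabilised by saturated ankle-torque feedback
so the model centre of pressure stays inside the foot, plus a hip/trunk
degree of freedom that drives the cervical joint centre.  Stepping trials
additionally execute a mediolateral weight shift, step-leg unloading
(SLU) and toe-off (TO) with event timings drawn from configurable
distributions (defaults: perturbation-to-TO 0.56 +/- 0.20 s, SLU-to-TO
0.16 +/- 0.03 s).

Whether a trial steps is decided by a latent per-subject force threshold
with logistic noise, so stepping probability rises monotonically with
perturbation force and the two classes overlap near the threshold.  An
alternative labelling rule thresholds the peak extrapolated-CoM (XCoM)
margin of a noise-free probe simulation, for experiments where the true
decision rule must be a known function of the mechanical state.

Force channels (per-foot vertical force and plate moments) are produced
at 1000 Hz, kinematic channels at 100 Hz, mirroring a force-plate plus
camera acquisition setup.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .anthropometry import SubjectAnthropometry, sample_anthropometry
from .response import BalanceResponse, write_cohort

__all__ = ["GeneratorConfig", "simulate_response", "generate_cohort", "write_cohort"]

G = 9.81  # gravitational acceleration, m/s^2

# Heights of landmarks as fractions of body height, used to place joints
# on the pendulum (de-facto standard segment proportions).
_H_CJC = 0.85
_H_HIP = 0.53
_H_KNEE = 0.285


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Magnitude-like parameters are fractions of body weight ``m*g``;
    times are seconds.  ``random_seed`` fixes the cohort bit-for-bit.
    """

    n_subjects: int = 10
    trials_per_subject: int = 20
    force_levels: tuple[float, ...] = (0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16)
    pulse_duration: float = 0.2
    force_threshold_mean: float = 0.11
    force_threshold_sd: float = 0.029
    decision_noise: float = 0.01  # logistic scale on the latent threshold, fraction of m*g

    # labelling rule: "force_threshold" (default) or "xcom_margin"
    label_rule: str = "force_threshold"
    xcom_margin_threshold: float = -0.155  # m, peak XCoM minus toe position
    # (mid-range of the peak-margin distribution spanned by the default
    # force levels, so both classes occur at every subject)
    xcom_margin_noise: float = 0.004  # m, logistic scale on the margin rule

    # event-timing model (means / sds in seconds)
    pert_to_to_mean: float = 0.56
    pert_to_to_sd: float = 0.20
    slu_to_to_mean: float = 0.16
    slu_to_to_sd: float = 0.03
    swing_mean: float = 0.18
    swing_sd: float = 0.03
    step_length_mean: float = 0.30
    step_length_sd: float = 0.05

    # noise amplitudes (set all to 0 for a noiseless cohort)
    process_noise: float = 0.7  # m/s^2, white accel noise driving postural sway
    kin_noise: float = 0.0015  # m, measurement noise on position channels
    force_noise: float = 2.0  # N, measurement noise on vertical forces
    share_noise: float = 0.006  # dimensionless, mediolateral load-share sway
    lean_sd: float = 0.008  # m, per-trial baseline lean offset

    # trial layout
    trial_duration: float = 6.5
    onset: float = 2.0
    force_rate: float = 1000.0
    kin_rate: float = 100.0

    # pendulum controller
    ankle_gain_p: float = 3.0
    ankle_gain_d: float = 0.45
    trunk_gain: float = 3.0
    trunk_gain_sd: float = 0.15
    trunk_step_factor: float = 1.3  # extra trunk response on stepping trials

    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("n_subjects and trials_per_subject must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        for name in (
            "force_threshold_sd",
            "decision_noise",
            "pert_to_to_sd",
            "slu_to_to_sd",
            "process_noise",
            "kin_noise",
            "force_noise",
            "share_noise",
            "lean_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.label_rule not in ("force_threshold", "xcom_margin"):
            raise ValueError(f"unknown label_rule {self.label_rule!r}")
        if not float(self.random_seed) == int(self.random_seed):
            raise ValueError("random_seed must be an integer")
        if self.onset < 2.0:
            raise ValueError("need >= 2 s of pre-perturbation baseline")
        if self.onset + 4.0 > self.trial_duration:
            raise ValueError("trial must cover 4 s after perturbation onset")

    def noiseless(self) -> "GeneratorConfig":
        """Copy of this config with every noise source switched off."""
        d = asdict(self)
        d.update(
            decision_noise=0.0,
            xcom_margin_noise=0.0,
            process_noise=0.0,
            kin_noise=0.0,
            force_noise=0.0,
            share_noise=0.0,
            lean_sd=0.0,
            trunk_gain_sd=0.0,
            force_threshold_sd=d["force_threshold_sd"],
        )
        return GeneratorConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["force_levels"] = list(d["force_levels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "force_levels" in d:
            d["force_levels"] = tuple(d["force_levels"])
        return cls(**d)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smooth_noise(rng: np.random.Generator, n: int, std: float, alpha: float = 0.01) -> np.ndarray:
    """Slow (exponentially smoothed) noise with approximately unit std, scaled."""
    white = rng.standard_normal(n)
    if std == 0.0:
        return np.zeros(n)
    from scipy.signal import lfilter

    smooth = lfilter([alpha], [1.0, -(1.0 - alpha)], white)
    scale = np.sqrt(alpha / 2.0)  # stationary std of the AR(1) filter
    return std * smooth / scale


def _integrate_pendulum(
    subject: SubjectAnthropometry,
    config: GeneratorConfig,
    pulse: np.ndarray,
    x0: float,
    accel_noise: np.ndarray,
    trunk_gain: float,
    t_to: float | None,
    step_length: float,
) -> dict[str, np.ndarray]:
    """Fixed-step (1000 Hz) integration of the ankle pendulum + trunk DoF.

    The ankle controller places the CoP at ``x0 + kp (x - x0) + kd xd``,
    clipped to the foot extents (after toe-off of a stepping trial the
    admissible CoP region extends to the new foot position and the gains
    stiffen to settle the recovery).  The trunk flexion angle responds to
    the perturbation as a damped second-order system.
    """
    n = len(pulse)
    dt = 1.0 / config.force_rate
    h = subject.com_height
    mass = subject.mass
    omega2 = G / h
    kp, kd = config.ankle_gain_p, config.ankle_gain_d
    p_lo, p_hi = subject.x_heel, subject.x_toe

    # trunk flexion dynamics
    w_t, zeta_t = 6.0, 0.7
    c_t = trunk_gain

    x = np.empty(n)
    v = np.empty(n)
    a = np.empty(n)
    cop = np.empty(n)
    phi = np.empty(n)
    phid = np.empty(n)

    xi, vi = x0, 0.0
    pi_, pdi = 0.0, 0.0
    i_to = int(round(t_to * config.force_rate)) if t_to is not None else n + 1
    for i in range(n):
        if i >= i_to:
            lo, hi = p_lo, step_length + subject.x_toe
            kp_i, kd_i = 5.0, 1.4
        else:
            lo, hi = p_lo, p_hi
            kp_i, kd_i = kp, kd
        p = x0 + kp_i * (xi - x0) + kd_i * vi
        if p < lo:
            p = lo
        elif p > hi:
            p = hi
        ai = omega2 * (xi - p) + pulse[i] / mass + accel_noise[i]
        vi += dt * ai
        xi += dt * vi
        x[i], v[i], a[i], cop[i] = xi, vi, ai, p

        phidd = -2.0 * zeta_t * w_t * pdi - w_t * w_t * pi_ + c_t * pulse[i] / mass
        pdi += dt * phidd
        pi_ += dt * pdi
        phi[i], phid[i] = pi_, pdi
    return {"x": x, "v": v, "a": a, "cop": cop, "phi": phi, "phid": phid}


def _stepping_share(
    t: np.ndarray, t_slu: float, t_to: float, t_land: float, sway: np.ndarray
) -> np.ndarray:
    """Load share carried by the stepping foot over a stepping trial.

    Baseline 0.5 with slow sway, a small anticipatory loading peak (0.55)
    reached exactly at SLU, a smooth monotone decline to zero at TO, an
    unloaded swing phase, and reloading to 0.5 after landing.
    """
    load_dur = 0.08
    peak_extra = 0.08  # anticipatory loading peak, fraction of body weight
    t1 = t_slu - load_dur
    reload_dur = 0.15

    share = 0.5 + sway
    # fade sway out before SLU so the decline is strictly monotone
    fade = np.clip((t_slu - t) / load_dur, 0.0, 1.0)
    in_event = (t >= t1) & (t < t_land + reload_dur)
    share = np.where(in_event, 0.5 + sway * fade, share)

    rise = (t >= t1) & (t < t_slu)
    share[rise] += peak_extra * _smoothstep((t[rise] - t1) / load_dur)

    fall = (t >= t_slu) & (t < t_to)
    u = (t[fall] - t_slu) / (t_to - t_slu)
    share[fall] = (0.5 + peak_extra) * 0.5 * (1.0 + np.cos(np.pi * u))

    swing = (t >= t_to) & (t < t_land)
    share[swing] = 0.0

    reload_ = (t >= t_land) & (t < t_land + reload_dur)
    share[reload_] = 0.5 * _smoothstep((t[reload_] - t_land) / reload_dur)
    return np.clip(share, 0.0, 1.0)


def simulate_response(
    subject: SubjectAnthropometry,
    force_magnitude: float,
    will_step: bool,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
    *,
    response_id: str = "R0001",
) -> BalanceResponse:
    """Simulate one balance response to a forward pelvis push.

    Parameters
    ----------
    force_magnitude : float
        Pulse amplitude in newtons (>= 0).
    will_step : bool
        Whether the trial executes a reactive step (weight shift, SLU,
        TO, swing and landing of the stepping foot).
    rng : numpy.random.Generator
        Source of all randomness for this trial.
    """
    if config is None:
        config = GeneratorConfig()
    if force_magnitude < 0:
        raise ValueError("force_magnitude must be >= 0")
    if not isinstance(subject, SubjectAnthropometry):
        raise TypeError("subject must be a SubjectAnthropometry")

    dt = 1.0 / config.force_rate
    n = int(round(config.trial_duration * config.force_rate))
    t = np.arange(n) * dt
    onset = config.onset
    decim = int(round(config.force_rate / config.kin_rate))

    # --- per-trial randomness (drawn in a fixed order) -----------------
    x0 = rng.normal(0.0, config.lean_sd) if config.lean_sd > 0 else 0.0
    trunk_gain = config.trunk_gain * max(0.1, rng.normal(1.0, config.trunk_gain_sd))
    stepping_foot = "l" if rng.random() < 0.5 else "r"
    to_rel = float(np.clip(rng.normal(config.pert_to_to_mean, config.pert_to_to_sd), 0.30, 1.90))
    # fast responses unload fast: cap the unloading duration so that even
    # the earliest prediction time step (TO - 1.5 * (TO - SLU)) stays
    # after perturbation onset
    slu_cap = min(0.30, (to_rel - 0.05) / 1.5)
    slu_dur = float(np.clip(rng.normal(config.slu_to_to_mean, config.slu_to_to_sd), 0.06, slu_cap))
    swing = float(np.clip(rng.normal(config.swing_mean, config.swing_sd), 0.10, 0.30))
    step_length = float(
        np.clip(
            rng.normal(config.step_length_mean, config.step_length_sd),
            max(0.15, 0.25 * subject.foot_length),
            0.45,
        )
    )
    accel_noise = (
        rng.normal(0.0, config.process_noise, n) if config.process_noise > 0 else np.zeros(n)
    )
    share_sway = _smooth_noise(rng, n, config.share_noise)
    # small within-foot mediolateral CoP jitter (m), only when sway noise is on
    cop_y_jitter = _smooth_noise(rng, n, 0.003 if config.share_noise > 0 else 0.0)

    if will_step:
        t_to = onset + to_rel
        t_slu = t_to - slu_dur
        t_land = t_to + swing
        trunk_gain *= config.trunk_step_factor
    else:
        t_to = t_slu = t_land = None

    # --- dynamics ------------------------------------------------------
    pulse = np.zeros(n)
    pulse[(t >= onset) & (t < onset + config.pulse_duration)] = force_magnitude
    state = _integrate_pendulum(
        subject, config, pulse, x0, accel_noise, trunk_gain, t_to, step_length
    )

    # --- ground reaction channels at 1000 Hz ---------------------------
    mg = subject.mass * G
    fz_tot = np.full(n, mg)
    if will_step:
        share = _stepping_share(t, t_slu, t_to, t_land, share_sway)
    else:
        share = 0.5 + share_sway
    fz_step = share * fz_tot
    fz_stance = fz_tot - fz_step
    if stepping_foot == "l":
        fz_l, fz_r = fz_step, fz_stance
        y_l, y_r = -subject.stance_width / 2.0, subject.stance_width / 2.0
    else:
        fz_l, fz_r = fz_stance, fz_step
        y_l, y_r = -subject.stance_width / 2.0, subject.stance_width / 2.0

    px = state["cop"]  # net anteroposterior CoP from the ankle controller
    py_l = y_l + cop_y_jitter
    py_r = y_r + cop_y_jitter
    my_l = -px * fz_l
    my_r = -px * fz_r
    mx_l = py_l * fz_l
    mx_r = py_r * fz_r

    with np.errstate(invalid="ignore", divide="ignore"):
        cop_y_net = np.where(fz_tot > 0, (mx_l + mx_r) / fz_tot, 0.0)

    force = {
        "fz_l": fz_l + (rng.normal(0.0, config.force_noise, n) if config.force_noise else 0.0),
        "fz_r": fz_r + (rng.normal(0.0, config.force_noise, n) if config.force_noise else 0.0),
        "mx_l": mx_l,
        "mx_r": mx_r,
        "my_l": my_l,
        "my_r": my_r,
        "pert_force": pulse,
    }

    # --- kinematic channels at 100 Hz ----------------------------------
    sl = slice(0, n, decim)
    t_kin = t[sl]
    x = state["x"][sl]
    v = state["v"][sl]
    a = state["a"][sl]
    phi = state["phi"][sl]
    phid = state["phid"][sl]
    h = subject.com_height
    H = subject.height

    i_com = 0.35 * subject.mass * h * h
    i_trunk = 0.05 * subject.mass * H * H
    k_com = i_com * (v / h) + i_trunk * phid

    x_cjc = (_H_CJC * H / h) * x + 0.30 * H * np.sin(phi)
    x_hip = (_H_HIP * H / h) * x
    x_knee = (_H_KNEE * H / h) * x

    nk = len(t_kin)
    ankle_stance = np.zeros(nk)
    ankle_step = np.zeros(nk)
    theta_knee = np.zeros(nk)
    if will_step:
        u = np.clip((t_kin - t_to) / max(t_land - t_to, 1e-6), 0.0, 1.0)
        ankle_step = step_length * _smoothstep(u)
        # slight knee flexion while the step leg unloads and swings
        uk = np.clip((t_kin - t_slu) / max(t_land - t_slu, 1e-6), 0.0, 1.0)
        theta_knee = 0.06 * np.sin(np.pi * np.clip(uk, 0.0, 1.0))
    if stepping_foot == "l":
        x_ankle_l, x_ankle_r = ankle_step, ankle_stance
    else:
        x_ankle_l, x_ankle_r = ankle_stance, ankle_step

    def meas(arr: np.ndarray) -> np.ndarray:
        if config.kin_noise:
            return arr + rng.normal(0.0, config.kin_noise, nk)
        return arr

    kin = {
        "x_com": meas(x),
        "xd_com": v,
        "xdd_com": a,
        "k_com": k_com,
        "x_cjc": meas(x_cjc),
        "x_hip": meas(x_hip),
        "x_knee": meas(x_knee),
        "x_ankle_l": meas(x_ankle_l),
        "x_ankle_r": meas(x_ankle_r),
        "theta_hip": phi + (rng.normal(0.0, config.kin_noise, nk) if config.kin_noise else 0.0),
        "theta_knee": theta_knee
        + (rng.normal(0.0, config.kin_noise, nk) if config.kin_noise else 0.0),
    }

    truth = {
        "will_step": bool(will_step),
        "force_magnitude": float(force_magnitude),
        "t_SLU": float(t_slu) if will_step else None,
        "t_TO": float(t_to) if will_step else None,
        "t_land": float(t_land) if will_step else None,
        "stepping_foot": stepping_foot if will_step else None,
        "step_length": float(step_length) if will_step else None,
        "cop_x": px.copy(),
        "cop_y": cop_y_net,
        "x_com_true": state["x"],
        "xd_com_true": state["v"],
    }

    return BalanceResponse(
        subject_id=subject.subject_id,
        response_id=response_id,
        onset=onset,
        t_force=t,
        force=force,
        t_kin=t_kin,
        kin=kin,
        label="stepping" if will_step else "non-stepping",
        truth=truth,
    )


def _peak_xcom_margin(subject: SubjectAnthropometry, force: float, config: GeneratorConfig) -> float:
    """Peak XCoM minus the toe position for a noise-free probe trial."""
    probe_cfg = config.noiseless()
    probe = simulate_response(
        subject, force, False, np.random.default_rng(0), probe_cfg, response_id="probe"
    )
    t = probe.t_kin
    mask = (t >= probe.onset) & (t <= probe.onset + 1.2)
    omega = np.sqrt(G / subject.com_height)
    xcom = probe.kin["x_com"][mask] + probe.kin["xd_com"][mask] / omega
    return float(np.max(xcom) - subject.x_toe)


def generate_cohort(
    config: GeneratorConfig,
    anthropometry: list[SubjectAnthropometry] | None = None,
) -> tuple[list[BalanceResponse], list[SubjectAnthropometry]]:
    """Generate a labeled cohort of stepping and non-stepping responses.

    Returns the responses together with the (possibly sampled)
    anthropometry table.  Fixing ``config.random_seed`` makes the output
    bit-identical across calls.
    """
    rng = np.random.default_rng(config.random_seed)
    if anthropometry is None:
        anthropometry = sample_anthropometry(config.n_subjects, rng)
    elif len(anthropometry) < 1:
        raise ValueError("need at least one subject")

    responses: list[BalanceResponse] = []
    counter = 0
    margin_cache: dict[tuple[str, float], float] = {}
    for subject in anthropometry:
        thr_frac = float(
            np.clip(
                rng.normal(config.force_threshold_mean, config.force_threshold_sd),
                0.02,
                0.30,
            )
        )
        mg = subject.mass * G
        levels = [
            config.force_levels[i % len(config.force_levels)]
            for i in range(config.trials_per_subject)
        ]
        for frac in levels:
            force = frac * mg
            if config.label_rule == "force_threshold":
                noise = rng.logistic(0.0, 1.0) if config.decision_noise > 0 else 0.0
                will_step = frac > thr_frac + config.decision_noise * noise
            else:
                key = (subject.subject_id, round(force, 6))
                if key not in margin_cache:
                    margin_cache[key] = _peak_xcom_margin(subject, force, config)
                noise = rng.logistic(0.0, 1.0) if config.xcom_margin_noise > 0 else 0.0
                will_step = (
                    margin_cache[key]
                    > config.xcom_margin_threshold + config.xcom_margin_noise * noise
                )
            counter += 1
            resp = simulate_response(
                subject,
                force,
                bool(will_step),
                rng,
                config,
                response_id=f"R{counter:04d}",
            )
            resp.truth["force_threshold"] = thr_frac
            responses.append(resp)
    return responses, anthropometry
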