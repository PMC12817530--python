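"""Synthetic cohorts and perturbation trials with known ground truth.

The generator emulates a two-group (chronic ankle instability vs healthy
control), three-session repeated-perturbation protocol on a translating
platform: each trial is a 5-s single-leg stance record (2-s baseline, 1-s
mediolateral sinusoidal platform displacement, 2-s recovery) with surface
EMG (TA/PL/SOL), vertical ground reaction force and centre of pressure,
segment kinematics and a platform accelerometer, each at its native rate.

The body is a linearized two-link frontal-plane inverted pendulum on the
moving base (ankle->hip link and hip->HAT lumped mass), driven by

* an ankle PD feedback torque on the mediolateral XCoM error (the CoP is
  back-computed from this torque via the massless-foot moment balance);
* a hip torque composed of a passive spring, a lagged reflexive damping
  pathway, and an open-loop command solved per analysis half-window so
  that the emitted hip torque correlates with the trial's margin of
  stability at a prescribed level rho (a template/noise mixture against
  the plant's measured linear responses);
* muscle activation envelopes derived from the ankle torque demand plus a
  common co-contraction floor c, so TA tracks the agonists exactly when
  c = 1 and shares nothing but the floor when c = 0.

Every stochastic element is driven by seeds derived from ``SimConfig.seed``
plus the participant id, session and attempt, so identical inputs yield
bit-identical trials.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .core import TimeSeries
from .errors import ConfigError
from .mechanics import GRAVITY, BodyModel

__all__ = [
    "EMG_RATE",
    "FORCE_RATE",
    "KIN_RATE",
    "ACCEL_RATE",
    "PerGroup",
    "ParticipantProfile",
    "SimConfig",
    "GroundTruth",
    "TrialRecording",
    "generate_cohort",
    "platform_trajectory",
    "simulate_trial",
    "reference_mos_template",
    "reference_templates",
    "RefTemplates",
    "body_model_for",
    "floor_for_cci",
]

# Native channel rates (Hz)
EMG_RATE = 1925.925
FORCE_RATE = 1000.0
KIN_RATE = 100.0
ACCEL_RATE = 370.3704

SIM_RATE = 2000.0        # internal fixed-step RK4 rate
BASELINE_DURATION = 2.0  # s of quiet stance before the perturbation
POST_DURATION = 2.0      # s after the perturbation
DIVERGENCE_ANGLE = 0.6   # rad; beyond this the trial is marked failed

Group = Literal["CAI", "HC"]


class PerGroup(NamedTuple):
    """A parameter with separate CAI and HC values."""

    cai: float | tuple
    hc: float | tuple

    def get(self, group: str):
        if group == "CAI":
            return self.cai
        if group == "HC":
            return self.hc
        raise ConfigError(f"unknown group {group!r}")


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's identity and anthropometrics."""

    id: str
    group: Group
    cait: int           # Cumberland Ankle Instability Tool score, 0-30
    mass: float         # kg
    height: float       # m
    leg_length: float   # m, ankle to hip
    test_side: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.group == "CAI" and not self.cait < 24:
            raise ConfigError("CAI requires CAIT < 24")
        if self.group == "HC" and self.cait != 30:
            raise ConfigError("HC requires CAIT = 30")
        if min(self.mass, self.height, self.leg_length) <= 0:
            raise ConfigError("mass, height and leg_length must be positive")


def floor_for_cci(cci_percent: float) -> float:
    """Nominal co-contraction floor c for a target CCI level (percent).

    On samples where the antagonist is purely agonist-locked (TA = c *
    agonist) the pointwise ratio min/(sum) is c/(1+c), giving CCI =
    200c/(1+c); inverting yields c = CCI/(200-CCI). The index measured on
    processed envelopes also reflects antagonist burst overlap and
    per-muscle normalization, so this mapping is nominal: it preserves
    ordering (higher floor, higher measured CCI) but not the absolute level.
    """
    if not (0 <= cci_percent < 200):
        raise ConfigError("target CCI must lie in [0, 200)")
    return cci_percent / (200.0 - cci_percent)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic protocol.

    Defaults encode the protocol: a 1-s, 0.017-m, 1-Hz mediolateral
    sinusoid followed by 7 s of quiet stance, three sessions, 22 CAI vs
    23 HC participants. Neuromuscular parameters encode the group/session
    structure of the study's outcomes: the healthy-control co-contraction
    floor declines across sessions while the CAI floor does not; the CAI
    group's MoS-hip coupling and stabilizing gains rise across sessions.
    """

    # cohort
    n_cai: int = 22
    n_hc: int = 23
    # platform protocol
    platform_amplitude: float = 0.017  # m
    platform_freq: float = 1.0         # Hz
    perturb_duration: float = 1.0      # s
    recovery_duration: float = 7.0     # s
    sessions: int = 3
    # co-contraction floor c; the measured index also reflects burst overlap
    # and normalization, so these are placed via the empirical c -> CCI map
    co_contraction_base: PerGroup = PerGroup(cai=0.30, hc=0.62)
    co_contraction_session_slope: PerGroup = PerGroup(cai=0.0, hc=-0.08)
    cait_cci_gain: float = 0.040       # floor increase per CAIT point below 24
    participant_cci_sd: float = 0.10   # between-participant floor SD
    muscle_tone: float = 0.08          # baseline activation fraction
    # ankle feedback (N*m per m of XCoM error; must exceed m*g to stabilize)
    ankle_gain: float = 1250.0
    ankle_damping: float = 320.0
    ankle_lag: float = 0.10   # s, first-order neuromuscular lag on the ankle drive
    ankle_gain_session_slope: PerGroup = PerGroup(cai=0.0, hc=0.0)
    # excessive velocity feedback inflates |XCoM - CoP|; practice tunes it
    # down in the CAI group, carrying the session decline in MoS
    ankle_damping_session_slope: PerGroup = PerGroup(cai=-60.0, hc=0.0)
    # hip command (N*m of emitted hip-torque rms)
    hip_gain: PerGroup = PerGroup(cai=9.0, hc=9.0)
    hip_gain_session_slope: PerGroup = PerGroup(cai=0.0, hc=0.0)
    hip_coupling: PerGroup = PerGroup(cai=0.30, hc=0.46)
    hip_coupling_session_slope: PerGroup = PerGroup(cai=0.10, hc=-0.03)
    hip_coupling_participant_sd: float = 0.08  # between-participant rho spread
    hip_coupling_trial_sd: float = 0.12        # trial-to-trial rho jitter
    # passive hip stabilization (always on; keeps the second mode bounded)
    hip_passive_stiffness: float = 250.0  # N*m/rad on theta2-theta1
    hip_passive_damping: float = 12.0     # N*m*s/rad, reflexive (lagged)
    hip_damping_lag: float = 0.03         # s, lag of the damping pathway
    # EMG synthesis
    emg_noise_rms: float = 5.0    # uV baseline noise
    emg_scale_uv: float = 300.0   # uV at unit activation
    torque_ref: float = 30.0      # N*m of ankle torque at unit activation demand
    # trial failure (Bernoulli per attempt), per group, one value per session
    fail_probability: PerGroup = PerGroup(cai=(0.60, 0.22, 0.18),
                                          hc=(0.55, 0.18, 0.15))
    # sensor noise
    accel_noise_rms: float = 0.02  # m/s^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cai <= 0 or self.n_hc <= 0:
            raise ConfigError("group sizes must be positive")
        if self.platform_amplitude <= 0:
            raise ConfigError("platform amplitude must be positive")
        if self.platform_freq <= 0 or self.perturb_duration <= 0:
            raise ConfigError("platform frequency and duration must be positive")
        if self.recovery_duration < 0 or self.sessions < 1:
            raise ConfigError("recovery duration >= 0 and sessions >= 1 required")
        for g in ("CAI", "HC"):
            probs = np.atleast_1d(np.asarray(self.fail_probability.get(g), dtype=float))
            if np.any((probs < 0) | (probs > 1)):
                raise ConfigError("failure probabilities must lie in [0, 1]")
            for per_group in (self.co_contraction_base, self.co_contraction_session_slope,
                              self.hip_gain, self.hip_gain_session_slope,
                              self.hip_coupling, self.hip_coupling_session_slope,
                              self.ankle_gain_session_slope,
                              self.ankle_damping_session_slope):
                if not np.isfinite(per_group.get(g)):
                    raise ConfigError("per-group parameters must be finite")

    @property
    def trial_duration(self) -> float:
        return BASELINE_DURATION + self.perturb_duration + POST_DURATION

    @property
    def perturb_onset(self) -> float:
        return BASELINE_DURATION

    def fail_prob(self, group: str, session: int) -> float:
        probs = np.atleast_1d(np.asarray(self.fail_probability.get(group), dtype=float))
        return float(probs[min(session - 1, probs.size - 1)])


@dataclass
class GroundTruth:
    """Latent per-trial records on the common 100-Hz 1-s window base."""

    time: np.ndarray                     # 101 window times, 0..1 s
    mos: np.ndarray                      # m
    ankle_torque: np.ndarray             # N*m, + = invertor
    hip_torque: np.ndarray               # N*m, + = adductor
    activations: dict[str, np.ndarray]   # TA/PL/SOL envelopes, fraction
    cci_level: float                     # prescribed co-contraction floor c
    coupling_rho: float                  # prescribed MoS-hip coupling
    com: np.ndarray                      # m, latent whole-body CoM
    xcom: np.ndarray                     # m
    cop: np.ndarray                      # m, lab frame
    ankle_torque_plate: np.ndarray | None = None  # N*m at force-plate samples, full trial


@dataclass
class TrialRecording:
    """All raw channels plus metadata for one perturbation cycle."""

    participant_id: str
    group: Group
    session: int
    attempt: int
    success: bool
    emg: dict[str, TimeSeries]           # TA/PL/SOL at 1925.925 Hz, uV
    grf_fz: TimeSeries                   # 1 kHz, N
    cop_platform: TimeSeries             # 1 kHz, m, platform-fixed frame
    kinematics: dict[str, TimeSeries]    # 100 Hz, m (platform_x/foot_x/hip_x/...)
    accel: TimeSeries                    # 370.3704 Hz, m/s^2 (platform)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def body_model_for(profile: ParticipantProfile) -> BodyModel:
    return BodyModel(mass=profile.mass, height=profile.height,
                     leg_length=profile.leg_length)


def generate_cohort(config: SimConfig) -> list[ParticipantProfile]:
    """Sample the two-group cohort; deterministic for a fixed seed.

    CAI participants draw integer CAIT scores in [13, 23] (mean near 17.6);
    controls are fixed at 30. Anthropometrics follow the cohort summary
    statistics (height ~1.72 m, mass ~70/65 kg).
    """
    rng = np.random.default_rng([config.seed, 0xC0])
    profiles: list[ParticipantProfile] = []
    specs = (("CAI", config.n_cai, 70.4, 9.3), ("HC", config.n_hc, 65.2, 8.5))
    for group, n, mass_mu, mass_sd in specs:
        for i in range(n):
            height = float(np.clip(rng.normal(1.72, 0.085), 1.50, 1.95))
            mass = float(np.clip(rng.normal(mass_mu, mass_sd), 45.0, 110.0))
            leg = float(height * 0.53 * rng.normal(1.0, 0.02))
            if group == "CAI":
                cait = int(np.clip(np.round(rng.normal(17.6, 4.1)), 13, 23))
            else:
                cait = 30
            side = "left" if rng.random() < 0.5 else "right"
            profiles.append(ParticipantProfile(
                id=f"{group}{i + 1:02d}", group=group, cait=cait, mass=mass,
                height=height, leg_length=leg, test_side=side))
    return profiles


# ---------------------------------------------------------------------------
# platform motion
# ---------------------------------------------------------------------------

def platform_trajectory(config: SimConfig, n_cycles: int, rate: float = FORCE_RATE) -> TimeSeries:
    """Repeated perturbation/recovery displacement profile.

    Each cycle is A*sin(2*pi*f*t) for the 1-s perturbation phase (first
    half-cycle medial, i.e. positive) followed by zeros for the recovery
    phase; the sinusoid starts and ends at zero so the profile is continuous.
    """
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    cycle = config.perturb_duration + config.recovery_duration
    n = int(round(n_cycles * cycle * rate)) + 1
    t = np.arange(n) / rate
    phase = np.mod(t, cycle)
    x = np.where(phase < config.perturb_duration,
                 config.platform_amplitude * np.sin(2 * np.pi * config.platform_freq * phase),
                 0.0)
    # the final sample of the last cycle belongs to recovery (displacement 0)
    return TimeSeries(x, rate=rate, t0=0.0, units="m")


def _platform_arrays(config: SimConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacement, velocity and acceleration of the platform at times t
    within a single 5-s trial (perturbation onset at BASELINE_DURATION).

    The displacement is the protocol sinusoid exactly; its velocity steps at
    the phase boundaries are handled as impulsive base-motion jumps by the
    integrator (see ``_integrate``), not smoothed away.
    """
    A = config.platform_amplitude
    w = 2 * np.pi * config.platform_freq
    tau = t - config.perturb_onset
    active = (tau >= 0) & (tau <= config.perturb_duration)
    p = np.where(active, A * np.sin(w * tau), 0.0)
    v = np.where(active, A * w * np.cos(w * tau), 0.0)
    a = np.where(active, -A * w * w * np.sin(w * tau), 0.0)
    return p, v, a


# ---------------------------------------------------------------------------
# dynamics kernel (fixed-step RK4 on the linearized two-link model)
# ---------------------------------------------------------------------------

def _rk4_kernel(n_steps, h, v_half, a_half, u_half, params, imp_idx, imp_dv):
    """Integrate the controlled two-link pendulum with fixed-step RK4.

    State: (theta1, theta2, w1, w2, q_a, q_h). q_a is the lagged ankle
    drive: the PD law acts on the mediolateral XCoM error (proportional)
    and the body-relative CoM velocity (damping), passed through a
    first-order neuromuscular lag so the ankle torque tau_a = -q_a stays
    continuous across the platform's velocity steps. q_h is the lagged hip
    damping pathway (reflexive rather than viscous), which keeps the hip
    torque continuous across the same velocity steps. Platform velocity/acceleration and the
    hip command are supplied at the half-step grid (2*n_steps + 1 samples).

    The protocol sinusoid steps the platform velocity at the phase
    boundaries; a rigid body riding the base receives the corresponding
    angular-velocity impulse dw = -M^-1 C dv, applied at the step indices
    in ``imp_idx`` with velocity jumps ``imp_dv``. Returns the state
    trajectory and the step index at which the lean angle diverged (-1 if
    it never did).
    """
    m11 = params[0]
    m12 = params[1]
    m22 = params[2]
    g1 = params[3]
    g2 = params[4]
    c1 = params[5]
    c2 = params[6]
    ka = params[7]
    da = params[8]
    khp = params[9]
    dhp = params[10]
    r_com1 = params[11]
    r_com2 = params[12]
    inv_w0 = params[13]
    inv_lag = params[14]
    inv_hlag = params[15]
    det = m11 * m22 - m12 * m12
    i11 = m22 / det
    i12 = -m12 / det
    i22 = m11 / det
    dw1_per_dv = -(i11 * c1 + i12 * c2)
    dw2_per_dv = -(i12 * c1 + i22 * c2)

    out = np.empty((n_steps + 1, 6))
    y = np.zeros(6)
    s = np.zeros(6)
    d = np.zeros(6)
    ks = np.zeros((4, 6))
    out[0] = y
    n_imp = imp_idx.shape[0]
    for k in range(n_steps):
        for j in range(n_imp):
            if imp_idx[j] == k:
                y[2] += dw1_per_dv * imp_dv[j]
                y[3] += dw2_per_dv * imp_dv[j]
        for stage in range(4):
            if stage == 0:
                for j in range(6):
                    s[j] = y[j]
                idx = 2 * k
            elif stage == 1:
                for j in range(6):
                    s[j] = y[j] + 0.5 * h * ks[0, j]
                idx = 2 * k + 1
            elif stage == 2:
                for j in range(6):
                    s[j] = y[j] + 0.5 * h * ks[1, j]
                idx = 2 * k + 1
            else:
                for j in range(6):
                    s[j] = y[j] + h * ks[2, j]
                idx = 2 * k + 2

            vp = v_half[idx]
            ap = a_half[idx]
            u = u_half[idx]
            com_off = r_com1 * s[0] + r_com2 * s[1]
            vrel = r_com1 * s[2] + r_com2 * s[3]
            e = com_off + (vp + vrel) * inv_w0
            drive = ka * e + da * vrel
            tau_a = -s[4]
            tau_h = -khp * (s[1] - s[0]) - s[5] + u
            rhs1 = g1 * s[0] + tau_a - tau_h - c1 * ap
            rhs2 = g2 * s[1] + tau_h - c2 * ap
            d[0] = s[2]
            d[1] = s[3]
            d[2] = i11 * rhs1 + i12 * rhs2
            d[3] = i12 * rhs1 + i22 * rhs2
            d[4] = (drive - s[4]) * inv_lag
            d[5] = (dhp * (s[3] - s[2]) - s[5]) * inv_hlag
            for j in range(6):
                ks[stage, j] = d[j]

        for j in range(6):
            y[j] += h / 6.0 * (ks[0, j] + 2 * ks[1, j] + 2 * ks[2, j] + ks[3, j])
        out[k + 1] = y
        if abs(y[0]) > 0.6:
            for kk in range(k + 2, n_steps + 1):
                out[kk] = y
            return out, k + 1
    return out, -1


try:  # optional JIT; a pure-Python fallback keeps the generator functional
    import numba as _numba

    _rk4_compiled = _numba.njit(cache=True)(_rk4_kernel)
except Exception:  # pragma: no cover - exercised only without numba
    _rk4_compiled = _rk4_kernel


class _SessionParams(NamedTuple):
    c_floor: float
    ankle_gain: float
    ankle_damping: float
    hip_gain: float
    rho: float


def _participant_traits(profile: ParticipantProfile, config: SimConfig) -> dict[str, float]:
    """Stable per-participant latent traits (same across sessions/attempts)."""
    tag = zlib.crc32(profile.id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([config.seed, 0x7A, tag])
    return {
        "cci_offset": float(rng.normal(0.0, config.participant_cci_sd)),
        "ankle_gain_mult": float(np.clip(rng.normal(1.0, 0.06), 0.8, 1.2)),
        "hip_gain_mult": float(np.clip(rng.normal(1.0, 0.10), 0.7, 1.3)),
        "rho_offset": float(rng.normal(0.0, config.hip_coupling_participant_sd)),
    }


def _session_params(profile: ParticipantProfile, config: SimConfig, session: int) -> _SessionParams:
    traits = _participant_traits(profile, config)
    g = profile.group
    s = session - 1
    c = (config.co_contraction_base.get(g)
         + config.co_contraction_session_slope.get(g) * s
         + traits["cci_offset"])
    if g == "CAI":
        c += config.cait_cci_gain * max(0, 24 - profile.cait)
    c = float(np.clip(c, 0.0, 1.0))
    ka = (config.ankle_gain + config.ankle_gain_session_slope.get(g) * s) * traits["ankle_gain_mult"]
    da = max(60.0, (config.ankle_damping + config.ankle_damping_session_slope.get(g) * s)
             * traits["ankle_gain_mult"])
    kh = max(0.0, (config.hip_gain.get(g) + config.hip_gain_session_slope.get(g) * s)
             * traits["hip_gain_mult"])
    rho = float(np.clip(config.hip_coupling.get(g)
                        + config.hip_coupling_session_slope.get(g) * s
                        + traits["rho_offset"], 0.0, 0.95))
    return _SessionParams(c_floor=c, ankle_gain=ka, ankle_damping=da,
                          hip_gain=kh, rho=rho)


def _model_params(model: BodyModel, config: SimConfig, ankle_gain: float,
                  ankle_damping: float | None = None) -> np.ndarray:
    m1, m2 = model.m_limb, model.m_hat
    a1, a2, L1 = model.a1, model.a2, model.leg_length
    m11 = m1 * a1 * a1 + m2 * L1 * L1 + model.j_limb
    m12 = m2 * L1 * a2
    m22 = m2 * a2 * a2 + model.j_hat
    g1 = model.g * (m1 * a1 + m2 * L1)
    g2 = model.g * m2 * a2
    c1 = m1 * a1 + m2 * L1
    c2 = m2 * a2
    r_com1 = (m1 * a1 + m2 * L1) / model.mass
    r_com2 = m2 * a2 / model.mass
    da = config.ankle_damping if ankle_damping is None else ankle_damping
    return np.array([
        m11, m12, m22, g1, g2, c1, c2,
        ankle_gain, da,
        config.hip_passive_stiffness, config.hip_passive_damping,
        r_com1, r_com2, 1.0 / model.omega0, 1.0 / config.ankle_lag,
        1.0 / config.hip_damping_lag,
    ])


def _integrate(model: BodyModel, config: SimConfig, ankle_gain: float,
               u_half: np.ndarray, ankle_damping: float | None = None) -> dict[str, np.ndarray]:
    """Run the RK4 kernel for one 5-s trial and derive latent signals."""
    n_steps = int(round(config.trial_duration * SIM_RATE))
    h = 1.0 / SIM_RATE
    t_half = np.arange(2 * n_steps + 1) * (h / 2.0)
    p_h, v_h, a_h = _platform_arrays(config, t_half)
    if ankle_damping is None:
        ankle_damping = config.ankle_damping
    params = _model_params(model, config, ankle_gain, ankle_damping)
    # base-velocity jumps of the protocol sinusoid at the phase boundaries
    w = 2 * np.pi * config.platform_freq
    dv = config.platform_amplitude * w
    imp_idx = np.array([
        int(round(config.perturb_onset * SIM_RATE)),
        int(round((config.perturb_onset + config.perturb_duration) * SIM_RATE)),
    ], dtype=np.int64)
    imp_dv = np.array([dv, -dv * np.cos(w * config.perturb_duration)])
    states, diverged_at = _rk4_compiled(n_steps, h, v_h, a_h, u_half, params,
                                        imp_idx, imp_dv)
    t = np.arange(n_steps + 1) * h
    p, v_p, a_p = _platform_arrays(config, t)
    th1, th2, w1, w2, q, qh = states.T
    r1 = params[11]
    r2 = params[12]
    com = p + r1 * th1 + r2 * th2
    vcom = v_p + r1 * w1 + r2 * w2
    tau_a_lag = -q
    u = u_half[::2]
    tau_h_lag = -config.hip_passive_stiffness * (th2 - th1) - qh + u
    fz = model.mass * model.g
    cop_lab = p - tau_a_lag / fz
    xcom_lat = com + vcom / model.omega0
    return {
        "t": t, "p": p, "theta1": th1, "theta2": th2, "w1": w1, "w2": w2,
        "com": com, "vcom": vcom, "xcom": xcom_lat, "cop": cop_lab,
        "tau_ankle": -tau_a_lag, "tau_hip": -tau_h_lag, "fz": fz,
        "diverged": diverged_at >= 0,
    }


def _window_times(config: SimConfig) -> np.ndarray:
    n = int(round(config.perturb_duration * KIN_RATE)) + 1
    return config.perturb_onset + np.arange(n) / KIN_RATE


class RefTemplates(NamedTuple):
    """Reference waveforms/responses over the perturbation window (pass 1).

    The linearized plant makes the emitted hip torque and (to first order)
    the margin of stability affine in the injected hip command, so a
    command-free run plus per-window template probes characterize how a
    pass-2 command shapes both. Everything is resolved separately for the
    two analysis windows (0-0.5 s and 0.5-1 s): the coupling prescription
    is enforced on exactly the windows the coupling analysis measures.
    """

    mos_template: np.ndarray    # standardized noise-free MoS shape (full window)
    mos_base: np.ndarray        # noise-free MoS waveform, m
    tau_base: np.ndarray        # hip torque with no command, N*m (+ = adductor)
    u_basis: np.ndarray         # (2, n) per-window composite commands
    tau_basis: np.ndarray       # (2, n) hip-torque responses to u_basis rows
    mos_basis: np.ndarray       # (2, n) MoS responses to u_basis rows


# analysis windows of the 101-node base (0.5-s boundary sample shared)
_W1 = slice(0, 51)
_W2 = slice(50, 101)


def _half_window_mask(n_win: int, half: int) -> np.ndarray:
    """Support mask with 100-ms cosine ramps for one half of the window."""
    mid = (n_win - 1) // 2
    mask = np.zeros(n_win)
    sl = slice(0, mid + 1) if half == 0 else slice(mid, n_win)
    m = np.zeros(mid + 1)
    tw = np.arange(mid + 1) / KIN_RATE
    ramp = np.minimum(1.0, np.minimum(tw, tw[-1] - tw) / 0.10)
    mask[sl] = 0.5 * (1 - np.cos(np.pi * np.clip(ramp, 0, 1)))
    return mask


def _u_half_from_window(u_win: np.ndarray, config: SimConfig, n_steps: int) -> np.ndarray:
    t_half = np.arange(2 * n_steps + 1) / (2 * SIM_RATE)
    return np.interp(t_half, _window_times(config), u_win, left=0.0, right=0.0)


def _window_response(model: BodyModel, config: SimConfig, pars: "_SessionParams",
                     u_win: np.ndarray):
    """Integrate one trial with the given windowed hip command; return the
    latent dict plus the windowed hip torque and MoS."""
    n_steps = int(round(config.trial_duration * SIM_RATE))
    latent = _integrate(model, config, pars.ankle_gain,
                        _u_half_from_window(u_win, config, n_steps),
                        ankle_damping=pars.ankle_damping)
    tw = _window_times(config)
    tau_win = np.interp(tw, latent["t"], latent["tau_hip"])
    mos_win = np.interp(tw, latent["t"], np.abs(latent["xcom"] - latent["cop"]))
    return latent, tau_win, mos_win


def reference_templates(profile: ParticipantProfile, config: SimConfig,
                        session: int) -> RefTemplates:
    """Command-free 'pass 1' of the simulator plus per-window probe responses.

    For each analysis half-window, the plant is probed with two tapered
    basis commands - the smoothed MoS shape and its time derivative (the
    derivative supplies the phase lead the plant filters away) - and the
    window-restricted MoS shape is regressed onto the two torque responses.
    The resulting composite command aligns its torque response with the MoS
    waveform inside that window, which is what lets pass 2 dial in a
    prescribed coupling there.
    """
    model = body_model_for(profile)
    pars = _session_params(profile, config, session)
    n_win = int(round(config.perturb_duration * KIN_RATE)) + 1
    _, tau_base, mos_base = _window_response(model, config, pars, np.zeros(n_win))
    template = mos_base - mos_base.mean()
    sd = template.std()
    template = template / sd if sd > 1e-12 else np.zeros_like(template)
    smooth_t = gaussian_filter1d(template, sigma=2.0, mode="nearest")
    d_template = np.gradient(smooth_t)
    dsd = d_template.std()
    d_template = d_template / dsd if dsd > 1e-12 else d_template

    u_rows, tau_rows, mos_rows = [], [], []
    for half, sl in enumerate((_W1, _W2)):
        mask = _half_window_mask(n_win, half)
        u1 = smooth_t * mask
        u2 = d_template * mask
        _, tau_1, mos_1 = _window_response(model, config, pars, u1)
        _, tau_2, mos_2 = _window_response(model, config, pars, u2)
        t1, t2 = tau_1 - tau_base, tau_2 - tau_base
        m1, m2 = mos_1 - mos_base, mos_2 - mos_base
        tw1 = t1[sl] - t1[sl].mean()
        tw2 = t2[sl] - t2[sl].mean()
        basis = np.vstack([tw1, tw2]).T
        target = template[sl] - template[sl].mean()
        coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
        u_c = coef[0] * u1 + coef[1] * u2
        tau_c = coef[0] * t1 + coef[1] * t2
        mos_c = coef[0] * m1 + coef[1] * m2
        scale = tau_c[sl].std()
        if scale > 1e-12:
            u_c, tau_c, mos_c = u_c / scale, tau_c / scale, mos_c / scale
        u_rows.append(u_c)
        tau_rows.append(tau_c)
        mos_rows.append(mos_c)
    return RefTemplates(mos_template=template, mos_base=mos_base,
                        tau_base=tau_base, u_basis=np.vstack(u_rows),
                        tau_basis=np.vstack(tau_rows), mos_basis=np.vstack(mos_rows))


def reference_mos_template(profile: ParticipantProfile, config: SimConfig,
                           session: int) -> np.ndarray:
    """Standardized noise-free MoS waveform over the perturbation window."""
    return reference_templates(profile, config, session).mos_template


# Sign of the MoS-locked hip-torque component: negative alignment (hip torque
# opposing MoS excursions) is the stabilizing direction for this plant. The
# measured coupling uses |r|, so the sign never reaches the analysis.
_COUPLING_SIGN = -1.0


def _solve_window(m: np.ndarray, t0: np.ndarray, tT: np.ndarray, tN: np.ndarray,
                  rho: float, S: float) -> tuple[float, float]:
    """Template/noise coefficients for one analysis window.

    Chooses (a, b) so that the window total t0 + a*tT + b*tN has component
    sign*rho*S along the standardized MoS shape m and orthogonal mean-square
    (1 - rho^2)*S^2 (i.e. correlation rho at centred rms S). If the mixture
    is unreachable the closest achievable orthogonal power is used.
    """
    n = m.size

    def centre(x):
        return x - x.mean()

    t0, tT, tN = centre(t0), centre(tT), centre(tN)
    p0, pT, pN = (np.dot(x, m) / n for x in (t0, tT, tN))
    if abs(pT) < 1e-9:
        return 0.0, 0.0
    q0, qT, qN = t0 - p0 * m, tT - pT * m, tN - pN * m
    a0 = (_COUPLING_SIGN * rho * S - p0) / pT
    a1 = -pN / pT
    w0 = q0 + a0 * qT
    w1 = qN + a1 * qT
    c2 = np.dot(w1, w1) / n
    c1 = 2.0 * np.dot(w0, w1) / n
    c0 = np.dot(w0, w0) / n - (1.0 - rho ** 2) * S * S
    disc = c1 * c1 - 4.0 * c2 * c0
    if c2 < 1e-12:
        b = 0.0
    elif disc >= 0:
        r1 = (-c1 + np.sqrt(disc)) / (2 * c2)
        r2 = (-c1 - np.sqrt(disc)) / (2 * c2)
        b = r1 if abs(r1) <= abs(r2) else r2
    else:
        b = -c1 / (2 * c2)
    return float(a0 + a1 * b), float(b)


def _solve_hip_command(ref: RefTemplates, tau_noise: np.ndarray,
                       mos_noise: np.ndarray, pars: _SessionParams) -> np.ndarray:
    """Coefficients (a1, b1, a2, b2) of the per-window hip command.

    By linearity the emitted hip torque is tau_base + a1*tauT1 + b1*tauN1 +
    a2*tauT2 + b2*tauN2 (and analogously for the MoS to first order). The
    two windows are solved in causal order - window-1 commands influence
    window 2, never the reverse - and the predicted MoS is refined by
    fixed-point iteration so the correlation target refers to the MoS the
    trial actually exhibits.
    """
    S = pars.hip_gain
    if S <= 0 or ref.mos_template.std() < 1e-12:
        return np.zeros(4)
    tauT1, tauT2 = ref.tau_basis
    mosT1, mosT2 = ref.mos_basis
    tauN1, tauN2 = tau_noise
    mosN1, mosN2 = mos_noise
    coefs = np.zeros(4)
    mos_pred = ref.mos_base.copy()
    for _ in range(4):
        m1 = mos_pred[_W1] - mos_pred[_W1].mean()
        sd1 = m1.std()
        if sd1 < 1e-12:
            break
        m1 /= sd1
        a1, b1 = _solve_window(m1, ref.tau_base[_W1], tauT1[_W1], tauN1[_W1],
                               pars.rho, S)
        base2 = ref.tau_base + a1 * tauT1 + b1 * tauN1
        mos_mid = ref.mos_base + a1 * mosT1 + b1 * mosN1
        m2 = mos_mid[_W2] - mos_mid[_W2].mean()
        sd2 = m2.std()
        if sd2 < 1e-12:
            break
        m2 /= sd2
        a2, b2 = _solve_window(m2, base2[_W2], tauT2[_W2], tauN2[_W2],
                               pars.rho, S)
        coefs = np.array([a1, b1, a2, b2])
        mos_pred = (ref.mos_base + a1 * mosT1 + b1 * mosN1
                    + a2 * mosT2 + b2 * mosN2)
    return coefs


def _emg_channels(act: dict[str, np.ndarray], t_act: np.ndarray, config: SimConfig,
                  rng: np.random.Generator, duration: float) -> dict[str, TimeSeries]:
    n = int(round(duration * EMG_RATE)) + 1
    t = np.arange(n) / EMG_RATE
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=EMG_RATE, output="sos")
    out: dict[str, TimeSeries] = {}
    for muscle in ("TA", "PL", "SOL"):
        carrier = sps.sosfilt(sos, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier ** 2))
        env = np.interp(t, t_act, act[muscle])
        samples = (env * carrier * config.emg_scale_uv
                   + rng.normal(0.0, config.emg_noise_rms, size=n))
        out[muscle] = TimeSeries(samples, rate=EMG_RATE, t0=0.0, units="uV")
    return out


def simulate_trial(
    profile: ParticipantProfile,
    config: SimConfig,
    session: int,
    attempt: int,
    template: "RefTemplates | None" = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one 5-s perturbation trial.

    ``template`` may carry the precomputed output of
    :func:`reference_templates` for this (participant, session); it is
    recomputed when absent. Identical arguments yield bit-identical outputs.
    """
    if not 1 <= session <= config.sessions:
        raise ConfigError(f"session must lie in 1..{config.sessions}")
    if attempt < 1:
        raise ConfigError("attempt index starts at 1")
    model = body_model_for(profile)
    pars = _session_params(profile, config, session)
    if template is None:
        template = reference_templates(profile, config, session)

    tag = zlib.crc32(profile.id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([config.seed, tag, session, attempt])
    rho_trial = float(np.clip(pars.rho + rng.normal(0.0, config.hip_coupling_trial_sd),
                              0.0, 0.95))
    pars = pars._replace(rho=rho_trial)

    # hip command: per-window template + smooth-noise mixtures solved
    # against the plant's measured responses so the emitted hip torque
    # carries the prescribed MoS coupling rho (at rms hip_gain) inside each
    # analysis half-window
    n_win = template.mos_template.size
    u_noise_rows, tau_n_rows, mos_n_rows = [], [], []
    for half in (0, 1):
        noise = gaussian_filter1d(rng.standard_normal(n_win), sigma=8.0,
                                  mode="nearest")
        noise = noise - noise.mean()
        nsd = noise.std()
        if nsd > 1e-12:
            noise /= nsd
        u_n = noise * _half_window_mask(n_win, half)
        _, tau_n, mos_n = _window_response(model, config, pars, u_n)
        u_noise_rows.append(u_n)
        tau_n_rows.append(tau_n - template.tau_base)
        mos_n_rows.append(mos_n - template.mos_base)
    coefs = _solve_hip_command(template, np.vstack(tau_n_rows),
                               np.vstack(mos_n_rows), pars)
    u_win = (coefs[0] * template.u_basis[0] + coefs[1] * u_noise_rows[0]
             + coefs[2] * template.u_basis[1] + coefs[3] * u_noise_rows[1])
    latent, _, _ = _window_response(model, config, pars, u_win)

    # ---- latent activations over the full trial (at 100 Hz) ------------
    t_act = np.arange(int(round(config.trial_duration * KIN_RATE)) + 1) / KIN_RATE
    tau_pub = np.interp(t_act, latent["t"], latent["tau_ankle"])
    d_pos = np.maximum(tau_pub, 0.0) / config.torque_ref
    d_neg = np.maximum(-tau_pub, 0.0) / config.torque_ref
    act_ag = config.muscle_tone + d_pos
    act_ta_own = config.muscle_tone + d_neg
    c = pars.c_floor
    act = {
        "PL": act_ag,
        "SOL": act_ag.copy(),
        "TA": c * act_ag + (1.0 - c) * act_ta_own,
    }

    # ---- emitted channels ----------------------------------------------
    emg = _emg_channels(act, t_act, config, rng, config.trial_duration)

    n_f = int(round(config.trial_duration * FORCE_RATE)) + 1
    t_f = np.arange(n_f) / FORCE_RATE
    fz = np.full(n_f, latent["fz"])
    tau_a_f = np.interp(t_f, latent["t"], latent["tau_ankle"])
    cop_platform = tau_a_f / fz  # platform-frame CoP; moment arm is frame-free
    grf_fz = TimeSeries(fz, rate=FORCE_RATE, units="N")
    cop_ts = TimeSeries(cop_platform, rate=FORCE_RATE, units="m")

    t_k = t_act
    p_k = np.interp(t_k, latent["t"], latent["p"])
    th1_k = np.interp(t_k, latent["t"], latent["theta1"])
    th2_k = np.interp(t_k, latent["t"], latent["theta2"])
    kin = {
        "platform_x": TimeSeries(p_k, rate=KIN_RATE, units="m"),
        "foot_x": TimeSeries(p_k, rate=KIN_RATE, units="m"),
        "limb_com_x": TimeSeries(p_k + model.a1 * th1_k, rate=KIN_RATE, units="m"),
        "hip_x": TimeSeries(p_k + model.leg_length * th1_k, rate=KIN_RATE, units="m"),
        "hat_com_x": TimeSeries(p_k + model.leg_length * th1_k + model.a2 * th2_k,
                                rate=KIN_RATE, units="m"),
    }

    n_acc = int(round(config.trial_duration * ACCEL_RATE)) + 1
    t_a = np.arange(n_acc) / ACCEL_RATE
    _, _, a_platform = _platform_arrays(config, t_a)
    accel = TimeSeries(a_platform + rng.normal(0.0, config.accel_noise_rms, n_acc),
                       rate=ACCEL_RATE, units="m/s^2")

    # ---- success flag ---------------------------------------------------
    if latent["diverged"]:
        success = False
    else:
        success = bool(rng.random() >= config.fail_prob(profile.group, session))

    # ---- ground truth on the window base --------------------------------
    tw = _window_times(config)
    mos_lat = np.abs(latent["xcom"] - latent["cop"])
    win = lambda y: np.interp(tw, latent["t"], y)
    act_win = {m: np.interp(tw, t_act, a) for m, a in act.items()}
    truth = GroundTruth(
        time=tw - config.perturb_onset,
        mos=win(mos_lat),
        ankle_torque=win(latent["tau_ankle"]),
        hip_torque=win(latent["tau_hip"]),
        activations=act_win,
        cci_level=c,
        coupling_rho=pars.rho,
        com=win(latent["com"]),
        xcom=win(latent["xcom"]),
        cop=win(latent["cop"]),
        ankle_torque_plate=tau_a_f,
    )
    rec = TrialRecording(
        participant_id=profile.id, group=profile.group, session=session,
        attempt=attempt, success=success, emg=emg, grf_fz=grf_fz,
        cop_platform=cop_ts, kinematics=kin, accel=accel)
    return rec, truth
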