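"""Centre of mass, extrapolated centre of mass, margin of stability and
frontal-plane ankle/hip torques.

Conventions
-----------
* +x is the medial direction of the stance limb; all positions are
  mediolateral coordinates in the lab frame.
* The base of support is the instantaneous centre-of-pressure point (not the
  foot boundary polygon), so the margin of stability is the absolute
  mediolateral distance between the extrapolated centre of mass (XCoM) and
  the CoP. A signed variant (+ = XCoM medial of the CoP) is available but is
  not used by default inference.
* Ankle torque is reported as ``Fz * (cop - ankle_x)`` (positive when the CoP
  sits medial of the ankle, i.e. an invertor torque resisting lateral CoP
  drift); hip torque follows the same sign convention through the
  Newton-Euler transport (positive = adductor).

The stance limb is modelled as one rigid link from ankle to hip carrying the
shank+thigh point mass, with the head-arms-trunk (plus swing leg) mass lumped
above the hip. The foot is treated as massless for the CoP <-> ankle-torque
mapping; its weight only enters the vertical force balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .errors import AlignmentError, ContactError, ModelError

__all__ = [
    "GRAVITY",
    "BodyModel",
    "MosSeries",
    "TorqueSeries",
    "com_trajectory",
    "xcom",
    "mos",
    "ankle_torque_frontal",
    "hip_torque_frontal",
]

GRAVITY = 9.81  # m/s^2

# Segment mass fractions (of body mass) and longitudinal CoM positions used
# throughout: foot; stance shank+thigh; head-arms-trunk including the hanging
# swing leg. The HAT offset above the hip is small because the swing leg
# pulls the lumped CoM down toward the hip.
FOOT_MASS_FRAC = 0.0145
LIMB_MASS_FRAC = 0.1465
LIMB_COM_FRAC = 0.55     # fraction of ankle->hip length, measured from ankle
HAT_OFFSET_FRAC = 0.075  # HAT(+swing leg) CoM height above hip, fraction of stature
LIMB_GYR_FRAC = 0.30     # limb radius of gyration about its CoM, fraction of leg length
HAT_GYR_FRAC = 0.25      # HAT(+swing leg) radius of gyration, fraction of stature


@dataclass(frozen=True)
class BodyModel:
    """Anthropometric model for the single-support frontal-plane analysis."""

    mass: float          # kg, whole body
    height: float        # m, stature
    leg_length: float    # m, ankle to hip
    foot_mass_frac: float = FOOT_MASS_FRAC
    limb_mass_frac: float = LIMB_MASS_FRAC
    limb_com_frac: float = LIMB_COM_FRAC
    hat_offset_frac: float = HAT_OFFSET_FRAC
    limb_gyr_frac: float = LIMB_GYR_FRAC
    hat_gyr_frac: float = HAT_GYR_FRAC
    g: float = GRAVITY

    def __post_init__(self) -> None:
        if min(self.mass, self.height, self.leg_length) <= 0:
            raise ModelError("mass, height and leg_length must be positive")
        if not (0 < self.foot_mass_frac < 1 and 0 < self.limb_mass_frac < 1):
            raise ModelError("segment mass fractions must lie in (0, 1)")
        if self.hat_mass_frac <= 0:
            raise ModelError("segment mass fractions must sum to < 1")

    # -- derived segment parameters -------------------------------------
    @property
    def hat_mass_frac(self) -> float:
        return 1.0 - self.foot_mass_frac - self.limb_mass_frac

    @property
    def m_foot(self) -> float:
        return self.foot_mass_frac * self.mass

    @property
    def m_limb(self) -> float:
        return self.limb_mass_frac * self.mass

    @property
    def m_hat(self) -> float:
        return self.hat_mass_frac * self.mass

    @property
    def a1(self) -> float:
        """Limb CoM distance from the ankle along the link (m)."""
        return self.limb_com_frac * self.leg_length

    @property
    def a2(self) -> float:
        """HAT CoM distance above the hip (m)."""
        return self.hat_offset_frac * self.height

    @property
    def j_limb(self) -> float:
        """Limb rotational inertia about its CoM (kg*m^2)."""
        return self.m_limb * (self.limb_gyr_frac * self.leg_length) ** 2

    @property
    def j_hat(self) -> float:
        """HAT(+swing leg) rotational inertia about its CoM (kg*m^2)."""
        return self.m_hat * (self.hat_gyr_frac * self.height) ** 2

    @property
    def com_height(self) -> float:
        """Whole-body CoM height above the ankle (m); pendulum length l."""
        return (self.m_limb * self.a1
                + self.m_hat * (self.leg_length + self.a2)) / self.mass

    @property
    def omega0(self) -> float:
        """Inverted-pendulum eigenfrequency sqrt(g/l) (rad/s)."""
        return float(np.sqrt(self.g / self.com_height))


@dataclass
class MosSeries:
    """Margin-of-stability waveform with its ingredients."""

    mos: TimeSeries   # m, |xcom - bos|
    xcom: TimeSeries  # m
    bos: TimeSeries   # m, mediolateral CoP
    signed: TimeSeries | None = None  # m, xcom - bos (+ = XCoM medial of CoP)


@dataclass
class TorqueSeries:
    """Frontal-plane joint torques on the common time base."""

    ankle_frontal: TimeSeries  # N*m, + = invertor
    hip_frontal: TimeSeries    # N*m, + = adductor


def _check_aligned(*series: TimeSeries) -> None:
    n = len(series[0])
    rate = series[0].rate
    for s in series[1:]:
        if len(s) != n or abs(s.rate - rate) > 1e-9 * rate:
            raise AlignmentError("waveforms must share one time base")


def com_trajectory(segments: dict[str, TimeSeries], model: BodyModel) -> TimeSeries:
    """Mass-weighted mediolateral whole-body CoM from segment CoM channels.

    ``segments`` must provide ``"foot_x"`` (platform/ankle level),
    ``"limb_com_x"`` and ``"hat_com_x"``.
    """
    required = ("foot_x", "limb_com_x", "hat_com_x")
    missing = [k for k in required if k not in segments]
    if missing:
        raise ModelError(f"missing segment channel(s): {missing}")
    _check_aligned(*(segments[k] for k in required))
    com = (model.foot_mass_frac * segments["foot_x"].samples
           + model.limb_mass_frac * segments["limb_com_x"].samples
           + model.hat_mass_frac * segments["hat_com_x"].samples)
    return segments["foot_x"].with_samples(com, units="m")


def xcom(com: TimeSeries, model: BodyModel, pendulum_length: float | None = None) -> TimeSeries:
    """Extrapolated centre of mass: XCoM = x + v / omega0.

    Velocity is obtained by central differences (one-sided at the edges).
    ``pendulum_length`` overrides the model's CoM height if given.
    """
    length = model.com_height if pendulum_length is None else pendulum_length
    if length <= 0:
        raise ModelError("pendulum length must be positive")
    omega0 = np.sqrt(model.g / length)
    v = np.gradient(com.samples, com.dt)
    return com.with_samples(com.samples + v / omega0, units="m")


def mos(xcom_series: TimeSeries, cop: TimeSeries, signed: bool = False) -> MosSeries:
    """Margin of stability relative to the instantaneous CoP."""
    _check_aligned(xcom_series, cop)
    diff = xcom_series.samples - cop.samples
    result = MosSeries(
        mos=xcom_series.with_samples(np.abs(diff), units="m"),
        xcom=xcom_series,
        bos=cop,
    )
    if signed:
        result.signed = xcom_series.with_samples(diff, units="m")
    return result


def ankle_torque_frontal(
    grf_fz: TimeSeries,
    cop: TimeSeries,
    ankle_x: TimeSeries,
    quasi_static: bool = True,
) -> TimeSeries:
    """Frontal-plane ankle torque from plate data (bottom-up, massless foot).

    tau = Fz * (cop - ankle_x). With the foot treated as massless the
    quasi-static and dynamic solutions coincide, so ``quasi_static`` is kept
    only as an interface knob.
    """
    _check_aligned(grf_fz, cop, ankle_x)
    fz = grf_fz.samples
    if np.any(fz <= 0):
        raise ContactError("vertical GRF must stay positive (no flight phase)")
    tau = fz * (cop.samples - ankle_x.samples)
    return grf_fz.with_samples(tau, units="N*m")


def hip_torque_frontal(
    grf_fz: TimeSeries,
    cop: TimeSeries,
    ankle_x: TimeSeries,
    hip_x: TimeSeries,
    limb_com_x: TimeSeries,
    hat_com_x: TimeSeries,
    model: BodyModel,
    quasi_static: bool = False,
) -> TimeSeries:
    """Frontal-plane hip torque by Newton-Euler transport along the stance limb.

    The ankle solution is transported to the hip across the single rigid
    ankle->hip link: the link's gravity moment and (unless ``quasi_static``)
    the inertial reactions of the limb and HAT masses are subtracted. Segment
    accelerations come from double differentiation of the kinematic channels.
    Positive output = adductor torque (same mediolateral sign convention as
    the ankle invertor torque).
    """
    _check_aligned(grf_fz, cop, ankle_x, hip_x, limb_com_x, hat_com_x)
    fz = grf_fz.samples
    if np.any(fz <= 0):
        raise ContactError("vertical GRF must stay positive (no flight phase)")

    dt = grf_fz.dt
    x_a = ankle_x.samples
    x_h = hip_x.samples
    x1 = limb_com_x.samples
    x2 = hat_com_x.samples
    m1, m2 = model.m_limb, model.m_hat
    a1, L1 = model.a1, model.leg_length

    if quasi_static:
        acc1 = np.zeros_like(x1)
        acc2 = np.zeros_like(x2)
        alpha1 = np.zeros_like(x1)
    else:
        acc1 = np.gradient(np.gradient(x1, dt), dt)
        acc2 = np.gradient(np.gradient(x2, dt), dt)
        theta1 = (x_h - x_a) / L1                    # small-angle limb lean
        alpha1 = np.gradient(np.gradient(theta1, dt), dt)

    # Link-1 moment balance about its CoM (small angles): ankle joint torque
    # + hip joint torque + joint-force moments = J1 * alpha1.
    tau_ankle_lag = -fz * (cop.samples - x_a)        # internal (lean-sense) torque
    f_ax = m1 * acc1 + m2 * acc2                     # horizontal ankle joint force
    f_az = fz - model.m_foot * model.g               # vertical force on the link
    tau_hip_lag = (tau_ankle_lag
                   - a1 * f_ax
                   + (x1 - x_a) * f_az
                   - (L1 - a1) * m2 * acc2
                   + (x_h - x1) * m2 * model.g
                   - model.j_limb * alpha1)
    return grf_fz.with_samples(-tau_hip_lag, units="N*m")
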