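"""CoM, XCoM, margin of stability and frontal-plane torque computations."""

import numpy as np
import pytest

from perturbalance.core import TimeSeries
from perturbalance.errors import AlignmentError, ContactError, DegenerateError, ModelError
from perturbalance.mechanics import (
    BodyModel,
    ankle_torque_frontal,
    com_trajectory,
    hip_torque_frontal,
    mos,
    xcom,
)
from perturbalance.synthdata import body_model_for, reference_templates, simulate_trial


@pytest.fixture(scope="module")
def model():
    return BodyModel(mass=70.0, height=1.72, leg_length=0.91)


def _ts(x, rate=100.0, units="m"):
    return TimeSeries(np.asarray(x, dtype=float), rate=rate, units=units)


class TestBodyModel:
    def test_mass_fractions_sum_to_one(self, model):
        assert model.foot_mass_frac + model.limb_mass_frac + model.hat_mass_frac \
            == pytest.approx(1.0)

    def test_com_height_is_plausible_pendulum_length(self, model):
        assert 0.45 * model.height < model.com_height < 0.65 * model.height

    def test_invalid_model_rejected(self):
        with pytest.raises(ModelError):
            BodyModel(mass=-1.0, height=1.7, leg_length=0.9)


class TestComTrajectory:
    def test_symmetric_zero(self, model):
        segs = {k: _ts(np.zeros(100)) for k in ("foot_x", "limb_com_x", "hat_com_x")}
        assert np.allclose(com_trajectory(segs, model).samples, 0.0)

    def test_weighted_mean(self, model):
        segs = {"foot_x": _ts(np.zeros(100)),
                "limb_com_x": _ts(np.zeros(100)),
                "hat_com_x": _ts(np.full(100, 0.1))}
        expected = model.hat_mass_frac * 0.1
        assert np.allclose(com_trajectory(segs, model).samples, expected)

    def test_missing_segment_is_model_error(self, model):
        with pytest.raises(ModelError):
            com_trajectory({"foot_x": _ts(np.zeros(100))}, model)

    def test_recovers_simulator_latent_com(self, trial, participant):
        rec, gt = trial
        model = body_model_for(participant)
        com = com_trajectory(rec.kinematics, model)
        t = com.times()
        sel = (t >= 2.0) & (t <= 3.0 + 1e-9)
        rmse = np.sqrt(np.mean((com.samples[sel] - gt.com) ** 2))
        assert rmse < 1e-3  # < 1 mm


class TestXcom:
    def test_constant_com_maps_to_itself(self, model):
        com = _ts(np.full(200, 0.07))
        assert np.allclose(xcom(com, model).samples, 0.07)

    def test_hand_value_with_unit_pendulum(self, model):
        """x = 0.10 m, v = 0.31321 m/s, l = 1 m -> XCoM = 0.20 m."""
        v = 0.31321
        t = np.arange(200) / 100.0
        com = _ts(0.10 + v * (t - 1.0))
        out = xcom(com, model, pendulum_length=1.0)
        omega0 = np.sqrt(model.g / 1.0)
        assert out.samples[100] == pytest.approx(0.10 + v / omega0, abs=1e-9)
        assert out.samples[100] == pytest.approx(0.20, abs=1e-3)

    def test_sinusoid_amplitude_scaling(self, model):
        """For com = A sin(2 pi f t), XCoM amplitude is
        A * sqrt(1 + (2 pi f / omega0)^2)."""
        f, A = 1.0, 0.02
        t = np.arange(0, 10, 0.01)
        out = xcom(_ts(A * np.sin(2 * np.pi * f * t)), model)
        expected = A * np.sqrt(1 + (2 * np.pi * f / model.omega0) ** 2)
        measured = np.abs(out.samples[100:-100]).max()
        assert abs(measured - expected) / expected < 0.01

    def test_stiff_pendulum_limit_collapses_onto_com(self, model):
        """As omega0 = sqrt(g/l) grows without bound (l -> 0), the velocity
        term v/omega0 vanishes and the XCoM coincides with the CoM."""
        t = np.arange(0, 5, 0.01)
        com = _ts(0.02 * np.sin(2 * np.pi * t))
        out = xcom(com, model, pendulum_length=1e-12)
        assert np.allclose(out.samples, com.samples, atol=1e-6)

    def test_nonpositive_length_rejected(self, model):
        with pytest.raises(ModelError):
            xcom(_ts(np.zeros(10)), model, pendulum_length=0.0)


class TestMos:
    def test_coincident_series_give_zero(self):
        a = _ts(np.linspace(0, 0.1, 50))
        assert np.allclose(mos(a, a).mos.samples, 0.0)

    def test_absolute_distance(self):
        x = _ts(np.full(50, 0.05))
        c = _ts(np.zeros(50))
        assert np.allclose(mos(x, c).mos.samples, 0.05)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(3)
        a = _ts(rng.standard_normal(80))
        b = _ts(rng.standard_normal(80))
        assert np.allclose(mos(a, b).mos.samples, mos(b, a).mos.samples)

    def test_non_negative_everywhere(self):
        rng = np.random.default_rng(4)
        a = _ts(rng.standard_normal(200))
        b = _ts(rng.standard_normal(200))
        assert (mos(a, b).mos.samples >= 0).all()

    def test_signed_variant(self):
        x = _ts(np.full(50, -0.02))
        c = _ts(np.zeros(50))
        out = mos(x, c, signed=True)
        assert np.allclose(out.signed.samples, -0.02)

    def test_alignment_enforced(self):
        with pytest.raises(AlignmentError):
            mos(_ts(np.zeros(50)), _ts(np.zeros(60)))


class TestAnkleTorque:
    def test_zero_moment_arm(self):
        fz = _ts(np.full(50, 700.0), units="N")
        x = _ts(np.full(50, 0.01))
        assert np.allclose(ankle_torque_frontal(fz, x, x).samples, 0.0)

    def test_hand_product(self):
        fz = _ts(np.full(50, 700.0), units="N")
        cop = _ts(np.full(50, 0.01))
        ankle = _ts(np.zeros(50))
        assert np.allclose(ankle_torque_frontal(fz, cop, ankle).samples, 7.0)

    def test_flight_phase_rejected(self):
        fz = _ts(np.zeros(50), units="N")
        x = _ts(np.zeros(50))
        with pytest.raises(ContactError):
            ankle_torque_frontal(fz, x, x)


class TestHipTorque:
    def test_static_upright_equilibrium(self, model):
        """CoP under the ankle, hip above the ankle, limb CoM on the
        ankle-hip line: the hip torque vanishes."""
        zeros = _ts(np.zeros(100))
        fz = _ts(np.full(100, model.mass * model.g), units="N")
        tau = hip_torque_frontal(fz, zeros, zeros, zeros, zeros, zeros, model)
        assert np.allclose(tau.samples, 0.0, atol=1e-10)

    def test_transported_term_linear_in_fz(self, model):
        """Under the quasi-static assumption the Fz-dependent transported
        part doubles when Fz doubles."""
        rng = np.random.default_rng(5)
        cop = _ts(0.01 * rng.standard_normal(100))
        ankle = _ts(np.zeros(100))
        hip = _ts(np.full(100, 0.004))
        x1 = _ts(np.full(100, 0.002))
        x2 = _ts(np.full(100, 0.006))
        const = (x1.samples - ankle.samples) * model.m_foot * model.g \
            - (hip.samples - x1.samples) * model.m_hat * model.g
        args = dict(ankle_x=ankle, hip_x=hip, limb_com_x=x1, hat_com_x=x2,
                    model=model, quasi_static=True)
        f1 = _ts(np.full(100, 700.0), units="N")
        f2 = _ts(np.full(100, 1400.0), units="N")
        t1 = hip_torque_frontal(f1, cop, **args).samples - const
        t2 = hip_torque_frontal(f2, cop, **args).samples - const
        assert np.allclose(t2, 2 * t1, atol=1e-9)

    def test_closure_on_simulated_trials(self, cohort, sim_config):
        """Recomputed hip torque matches the simulator's latent torque to
        within 2% RMSE of its peak (small batch; the full 50-trial batch
        runs in the acceptance suite)."""
        errs = []
        for p in cohort[:3]:
            ref = reference_templates(p, sim_config, 1)
            model = body_model_for(p)
            for attempt in (1, 2):
                rec, gt = simulate_trial(p, sim_config, 1, attempt, template=ref)
                kin = rec.kinematics
                n = len(kin["platform_x"])
                fz = TimeSeries(rec.grf_fz.resample(100.0).samples[:n],
                                rate=100.0, units="N")
                cop = TimeSeries(
                    rec.cop_platform.resample(100.0).samples[:n]
                    + kin["platform_x"].samples, rate=100.0, units="m")
                tau = hip_torque_frontal(fz, cop, kin["platform_x"], kin["hip_x"],
                                         kin["limb_com_x"], kin["hat_com_x"], model)
                t = tau.times()
                sel = (t >= 2.0) & (t <= 3.0 + 1e-9)
                resid = tau.samples[sel] - gt.hip_torque
                errs.append(np.sqrt(np.mean(resid ** 2))
                            / np.abs(gt.hip_torque).max())
        assert max(errs) < 0.02

    def test_static_consistency_of_ankle_solution(self, model):
        """On a zero-motion segment the ankle torque equals
        Fz * (cop - ankle) exactly."""
        fz = _ts(np.full(60, 686.7), units="N")
        cop = _ts(np.full(60, 0.013))
        ankle = _ts(np.full(60, 0.002))
        tau = ankle_torque_frontal(fz, cop, ankle)
        assert np.allclose(tau.samples, 686.7 * 0.011)
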