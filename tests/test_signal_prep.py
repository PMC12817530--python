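"""EMG conditioning, QC, onset detection and window extraction."""

import numpy as np
import pytest

from perturbalance.core import TimeSeries
from perturbalance.errors import (
    BoundsError,
    DataError,
    DegenerateError,
    SamplingRateError,
    SyncError,
)
from perturbalance.signal_prep import (
    compute_snr,
    detect_onsets,
    emg_envelope,
    extract_window,
    normalize_envelopes,
    qc_check,
    rms,
)

EMG_FS = 1925.925


def _sine(freq, amp, duration=4.0, fs=EMG_FS):
    t = np.arange(int(duration * fs)) / fs
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), rate=fs, units="uV")


class TestEmgEnvelope:
    def test_passband_sine_plateau_matches_rectified_mean(self):
        """A 50-Hz sinusoid of amplitude a has rectified mean 2a/pi; the
        20-Hz envelope plateau must land within 5% of it."""
        a = 100.0
        env = emg_envelope(_sine(50.0, a))
        mid = env.samples[len(env) // 4: -len(env) // 4]
        assert np.abs(mid.mean() - 2 * a / np.pi) / (2 * a / np.pi) < 0.05

    def test_all_zero_input(self):
        ts = TimeSeries(np.zeros(8000), rate=EMG_FS, units="uV")
        assert np.allclose(emg_envelope(ts).samples, 0.0)

    def test_below_band_rejection(self):
        """A 5-Hz sinusoid sits below the 10-Hz band edge and must be
        suppressed to under 1% of the input RMS."""
        ts = _sine(5.0, 100.0)
        env = emg_envelope(ts)
        mid = env.samples[len(env) // 4: -len(env) // 4]
        assert rms(mid) < 0.01 * rms(ts.samples)

    def test_rate_too_low_rejected(self):
        ts = TimeSeries(np.zeros(1000), rate=500.0, units="uV")
        with pytest.raises(SamplingRateError):
            emg_envelope(ts)

    def test_envelope_filtering_near_idempotent(self):
        """Re-low-passing an already envelope-band signal moves the plateau
        by under 1%."""
        from scipy import signal as sps
        env = emg_envelope(_sine(50.0, 100.0))
        sos = sps.butter(4, 20.0, btype="lowpass", fs=EMG_FS, output="sos")
        twice = sps.sosfiltfilt(sos, env.samples)
        sl = slice(len(env) // 4, -len(env) // 4)
        assert np.abs(twice[sl].mean() - env.samples[sl].mean()) \
            < 0.01 * env.samples[sl].mean()


class TestNormalization:
    def _env(self, peak, n=200):
        x = np.linspace(0, np.pi, n)
        return TimeSeries(peak * np.sin(x) ** 2, rate=100.0, units="uV")

    def test_single_trial_self_normalizes(self):
        out = normalize_envelopes([{"TA": self._env(80.0)}])
        assert out[0]["TA"].samples.max() == pytest.approx(1.0)

    def test_two_trial_maximum_reference(self):
        out = normalize_envelopes([{"TA": self._env(40.0)}, {"TA": self._env(80.0)}])
        assert out[0]["TA"].samples.max() == pytest.approx(0.5)
        assert out[1]["TA"].samples.max() == pytest.approx(1.0)

    def test_bounds_and_unit_max(self):
        out = normalize_envelopes(
            [{"TA": self._env(p)} for p in (10.0, 55.0, 80.0)])
        stacked = np.concatenate([o["TA"].samples for o in out])
        assert stacked.min() >= 0.0 and stacked.max() == pytest.approx(1.0)

    def test_failed_trials_rejected(self):
        with pytest.raises(DataError):
            normalize_envelopes([{"TA": self._env(80.0)}], success_flags=[False])

    def test_zero_maximum_rejected(self):
        flat = TimeSeries(np.zeros(50), rate=100.0, units="uV")
        with pytest.raises(DegenerateError):
            normalize_envelopes([{"TA": flat}])


class TestSnrAndQc:
    def _const(self, level, n=1000):
        rng = np.random.default_rng(0)
        x = level * np.sign(rng.standard_normal(n))  # RMS exactly `level`
        return TimeSeries(x, rate=EMG_FS, units="uV")

    def test_log_identities(self):
        assert compute_snr(self._const(10.0), self._const(1.0)) == pytest.approx(20.0)
        assert compute_snr(self._const(3.0), self._const(3.0)) == pytest.approx(0.0)

    def test_zero_baseline_rejected(self):
        flat = TimeSeries(np.zeros(100), rate=EMG_FS, units="uV")
        with pytest.raises(DegenerateError):
            compute_snr(self._const(10.0), flat)

    def test_qc_example_passes(self):
        report = qc_check("TA", self._const(3.0), self._const(30.0))
        assert report.snr_db == pytest.approx(20.0)
        assert report.baseline_rms == pytest.approx(3.0)
        assert report.passed

    @pytest.mark.parametrize("baseline_uv,ratio_db,expected", [
        (3.0, 20.0, True),    # both criteria met
        (20.0, 20.0, False),  # baseline RMS too high
        (3.0, 5.0, False),    # SNR too low
        (20.0, 5.0, False),   # both violated
        (14.9, 10.1, True),   # just inside both thresholds
        (15.1, 10.1, False),  # RMS boundary is strict
        (14.9, 9.9, False),   # SNR boundary is strict
    ])
    def test_qc_rule_is_exact_conjunction(self, baseline_uv, ratio_db, expected):
        contraction = self._const(baseline_uv * 10 ** (ratio_db / 20.0))
        report = qc_check("PL", self._const(baseline_uv), contraction)
        assert report.passed == expected


class TestOnsetDetection:
    ACC_FS = 370.3704

    def _impulse_channel(self, times, duration=12.0):
        n = int(duration * self.ACC_FS)
        x = np.zeros(n)
        for t in times:
            x[int(t * self.ACC_FS)] = 5.0
        return TimeSeries(x, rate=self.ACC_FS, units="m/s^2")

    def test_impulses_found_at_their_times(self):
        accel = self._impulse_channel([2.0, 10.0])
        onsets = detect_onsets(accel, target_rate=EMG_FS, n_expected=2)
        assert onsets[0] == pytest.approx(2.0, abs=1.5 / EMG_FS + 1 / self.ACC_FS)
        assert onsets[1] == pytest.approx(10.0, abs=1.5 / EMG_FS + 1 / self.ACC_FS)

    def test_flat_channel_is_sync_error(self):
        flat = TimeSeries(np.zeros(1000), rate=self.ACC_FS, units="m/s^2")
        with pytest.raises(SyncError):
            detect_onsets(flat, target_rate=EMG_FS, n_expected=1)

    def test_too_few_bursts_reported(self):
        accel = self._impulse_channel([2.0])
        with pytest.raises(SyncError, match="found 1"):
            detect_onsets(accel, target_rate=EMG_FS, n_expected=2)

    def test_sinusoid_episode_peak_at_quarter_period(self):
        """Sinusoidal displacement has acceleration extrema a quarter and
        three quarters into the episode; the reported onset must be one of
        them, within 0.25 s of episode start."""
        t = np.arange(int(12.0 * self.ACC_FS)) / self.ACC_FS
        a = np.where((t >= 3.0) & (t <= 4.0),
                     -0.017 * (2 * np.pi) ** 2 * np.sin(2 * np.pi * (t - 3.0)), 0.0)
        accel = TimeSeries(a, rate=self.ACC_FS, units="m/s^2")
        onset = detect_onsets(accel, target_rate=EMG_FS, n_expected=1)[0]
        assert min(abs(onset - 3.25), abs(onset - 3.75)) < 0.01

    @pytest.mark.parametrize("shift", [0.5, 1.7])
    def test_shift_equivariance(self, shift):
        base = self._impulse_channel([2.0, 10.0])
        shifted = TimeSeries(base.samples, rate=base.rate, t0=shift,
                             units=base.units)
        o0 = detect_onsets(base, target_rate=EMG_FS, n_expected=2)
        o1 = detect_onsets(shifted, target_rate=EMG_FS, n_expected=2)
        assert np.allclose(np.array(o1) - np.array(o0), shift,
                           atol=1.5 / EMG_FS)


class TestExtractWindow:
    def test_one_second_window_has_101_samples(self):
        ts = TimeSeries(np.arange(5001, dtype=float), rate=1000.0, units="m")
        win = extract_window(ts, onset=2.0, duration=1.0, out_rate=100.0)
        assert len(win) == 101
        assert win.t0 == 0.0

    def test_out_of_bounds_rejected(self):
        ts = TimeSeries(np.zeros(500), rate=100.0, units="m")
        with pytest.raises(BoundsError):
            extract_window(ts, onset=4.9, duration=1.0)

    def test_constant_series_preserved(self):
        ts = TimeSeries(np.full(2000, 3.3), rate=1000.0, units="m")
        win = extract_window(ts, onset=0.3, duration=1.0, out_rate=100.0)
        assert np.allclose(win.samples, 3.3)
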