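"""Raw-channel conditioning: EMG envelopes, normalization, QC,
accelerometer-based perturbation-onset detection and window extraction.

EMG processing follows the standard linear-envelope chain: zero-phase
4th-order Butterworth band-pass (10-400 Hz), full-wave rectification,
zero-phase 4th-order Butterworth low-pass at 20 Hz, then amplitude
normalization to the maximum envelope value across a participant's
successful trials. Zero-phase (forward-backward) filtering is the default
because envelope timing feeds the 1D waveform statistics; a causal variant
is available via ``zero_phase=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import TimeSeries
from .errors import (
    BoundsError,
    DataError,
    DegenerateError,
    SamplingRateError,
    SyncError,
)

__all__ = [
    "QcReport",
    "emg_envelope",
    "normalize_envelopes",
    "compute_snr",
    "qc_check",
    "detect_onsets",
    "extract_window",
    "rms",
]

BASELINE_RMS_LIMIT_UV = 15.0  # uV
SNR_LIMIT_DB = 10.0           # dB


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(np.asarray(x, dtype=float)))))


@dataclass(frozen=True)
class QcReport:
    """Electrode quality check: baseline RMS below 15 uV and SNR above 10 dB."""

    channel: str
    baseline_rms: float  # uV
    snr_db: float        # dB

    @property
    def passed(self) -> bool:
        return self.baseline_rms < BASELINE_RMS_LIMIT_UV and self.snr_db > SNR_LIMIT_DB


def emg_envelope(
    raw: TimeSeries,
    band: tuple[float, float] = (10.0, 400.0),
    lowpass: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> TimeSeries:
    """Linear envelope of a raw EMG channel.

    Band-pass -> full-wave rectification -> low-pass, with a final clamp at
    zero (zero-phase low-pass filtering can undershoot slightly). Output has
    the same rate and length as the input.
    """
    if raw.rate <= 2 * band[1]:
        raise SamplingRateError(
            f"EMG rate {raw.rate} Hz too low for a {band[1]} Hz band edge")
    if not np.isfinite(raw.samples).all():  # pragma: no cover - TimeSeries checks too
        raise DataError("EMG contains non-finite samples")
    sos_bp = sps.butter(order, band, btype="bandpass", fs=raw.rate, output="sos")
    sos_lp = sps.butter(order, lowpass, btype="lowpass", fs=raw.rate, output="sos")
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    bandpassed = filt(sos_bp, raw.samples)
    envelope = filt(sos_lp, np.abs(bandpassed))
    return raw.with_samples(np.clip(envelope, 0.0, None))


def normalize_envelopes(
    trial_envelopes: list[dict[str, TimeSeries]],
    success_flags: list[bool] | None = None,
) -> list[dict[str, TimeSeries]]:
    """Normalize each muscle's envelopes by the participant's maximum over
    all successful trials.

    ``trial_envelopes`` holds one dict per trial mapping muscle name to its
    envelope. All supplied trials form the normalization set and must be
    successful: pass ``success_flags`` to assert this contract explicitly
    (any failed trial in the set is an error, since the reference maximum is
    defined over successful perturbation trials only).

    Returns per-trial dicts of normalized envelopes (unitless, in [0, 1];
    the set maximum maps to exactly 1 per muscle).
    """
    if not trial_envelopes:
        raise DegenerateError("normalization requires at least one trial")
    if success_flags is not None:
        if len(success_flags) != len(trial_envelopes):
            raise DataError("success_flags length mismatch")
        if not all(success_flags):
            raise DataError(
                "normalization set must contain successful trials only")
    muscles = trial_envelopes[0].keys()
    maxima: dict[str, float] = {}
    for muscle in muscles:
        peak = max(float(t[muscle].samples.max()) for t in trial_envelopes)
        if peak <= 0:
            raise DegenerateError(f"zero envelope maximum for muscle {muscle}")
        maxima[muscle] = peak
    return [
        {m: ts.with_samples(ts.samples / maxima[m], units="fraction of max")
         for m, ts in trial.items()}
        for trial in trial_envelopes
    ]


def compute_snr(contraction: TimeSeries, baseline: TimeSeries) -> float:
    """Signal-to-noise ratio 20*log10(RMS_contraction / RMS_baseline) in dB."""
    rms_b = rms(baseline.samples)
    if rms_b <= 0:
        raise DegenerateError("baseline RMS is zero; SNR undefined")
    return 20.0 * np.log10(rms(contraction.samples) / rms_b)


def qc_check(channel: str, baseline: TimeSeries, contraction: TimeSeries) -> QcReport:
    """Electrode QC from a quiet baseline segment and a contraction segment."""
    return QcReport(channel=channel, baseline_rms=rms(baseline.samples),
                    snr_db=compute_snr(contraction, baseline))


def detect_onsets(
    accel: TimeSeries,
    target_rate: float,
    n_expected: int,
    threshold_mult: float = 5.0,
    min_gap: float = 1.0,
) -> list[float]:
    """Perturbation onsets from the platform accelerometer.

    The channel is linearly resampled to ``target_rate`` (time alignment to
    the EMG clock), thresholded at ``threshold_mult`` times the robust
    baseline RMS, suprathreshold samples are grouped into bursts separated
    by at least ``min_gap`` seconds, and each onset is the time of peak
    |acceleration| within its burst. Exactly ``n_expected`` strictly
    increasing onset times are returned (the strongest bursts win if more
    are found).
    """
    if n_expected < 1:
        raise SyncError("n_expected must be >= 1")
    res = accel.resample(target_rate)
    mag = np.abs(res.samples)
    # robust baseline: median |a| of the channel, scaled to RMS under
    # Gaussian noise; falls back to a fraction of the peak for noise-free
    # synthetic impulse channels
    baseline = np.median(mag) / 0.6745
    peak = mag.max()
    if peak <= 0:
        raise SyncError("flat accelerometer channel; found 0 bursts")
    threshold = threshold_mult * baseline
    if threshold <= 0 or threshold >= peak:
        threshold = 0.5 * peak
    above = mag >= threshold
    if not above.any():
        raise SyncError("no suprathreshold accelerometer activity; found 0 bursts")
    idx = np.flatnonzero(above)
    gap = max(1, int(round(min_gap * target_rate)))
    splits = np.flatnonzero(np.diff(idx) > gap)
    bursts = np.split(idx, splits + 1)
    peaks = []
    for burst in bursts:
        k = burst[np.argmax(mag[burst])]
        peaks.append((mag[k], res.t0 + k / target_rate))
    if len(peaks) < n_expected:
        raise SyncError(
            f"expected {n_expected} perturbation bursts, found {len(peaks)}")
    peaks.sort(key=lambda p: -p[0])
    onsets = sorted(t for _, t in peaks[:n_expected])
    return onsets


def extract_window(
    ts: TimeSeries,
    onset: float,
    duration: float,
    out_rate: float = 100.0,
) -> TimeSeries:
    """Resample ``[onset, onset + duration]`` onto the common analysis base.

    Output has ``duration * out_rate + 1`` samples and t0 = 0.
    """
    eps = 0.5 * ts.dt
    if onset < ts.t0 - eps or onset + duration > ts.t_end + eps:
        raise BoundsError(
            f"window [{onset}, {onset + duration}] s exceeds recording "
            f"[{ts.t0}, {ts.t_end}] s")
    n = int(round(duration * out_rate)) + 1
    t = onset + np.arange(n) / out_rate
    return TimeSeries(ts.interp_at(t), rate=out_rate, t0=0.0, units=ts.units)
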