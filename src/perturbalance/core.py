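"""Uniformly sampled time-series carrier shared by every pipeline stage.

All raw and derived signals (EMG, ground reaction force, centre of pressure,
kinematic channels, accelerometer, margin-of-stability and torque waveforms)
travel through :class:`TimeSeries`: a 1-D float array with a sampling rate,
a start time and a unit string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BoundsError, DataError

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples:
        Signal values; converted to a float64 vector. Must be finite and
        contain at least two samples.
    rate:
        Sampling rate in Hz (> 0).
    t0:
        Time of the first sample in seconds.
    units:
        Free-form unit string carried through processing (e.g. ``"uV"``,
        ``"m"``, ``"N*m"``).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise DataError("TimeSeries requires a 1-D vector of length >= 2")
        if not np.isfinite(self.samples).all():
            raise DataError("TimeSeries samples must be finite")
        if not (self.rate > 0):
            raise DataError(f"sampling rate must be positive, got {self.rate}")

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (len(self) - 1) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    # -- transforms ------------------------------------------------------
    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "TimeSeries":
        """Same clock, new values."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       units=self.units if units is None else units)

    def interp_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times within the span."""
        return np.interp(t, self.times(), self.samples)

    def resample(self, rate: float) -> "TimeSeries":
        """Linear-interpolation resample onto a new uniform grid.

        The new grid starts at ``t0`` and covers the same span (last grid
        point <= t_end).
        """
        if not (rate > 0):
            raise DataError("target rate must be positive")
        n = int(np.floor(self.duration * rate)) + 1
        t_new = self.t0 + np.arange(n) / rate
        return TimeSeries(self.interp_at(t_new), rate=rate, t0=self.t0, units=self.units)

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series between two times (inclusive of covered samples)."""
        eps = 0.5 * self.dt
        if t_start < self.t0 - eps or t_end > self.t_end + eps:
            raise BoundsError(
                f"requested [{t_start}, {t_end}] s outside recording "
                f"[{self.t0}, {self.t_end}] s"
            )
        i0 = int(np.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = int(np.floor((t_end - self.t0) * self.rate + 1e-9)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, len(self))
        return TimeSeries(self.samples[i0:i1], rate=self.rate,
                          t0=self.t0 + i0 / self.rate, units=self.units)
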