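"""MoS-torque coordination: zero-lag cross-correlation over half-second
windows with strength categorization.

For each trial the margin-of-stability waveform is correlated with the
frontal-plane ankle and hip torque over two windows (0-0.5 s and 0.5-1 s of
the perturbation). The zero-lag value of the normalized cross-correlation of
two mean-removed series is the Pearson correlation of the windowed samples;
its absolute value is categorized as strong (>= 0.5), moderate (>= 0.3) or
weak (< 0.3), boundaries assigned to the upper class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DegenerateError
from .mechanics import MosSeries, TorqueSeries

__all__ = ["CouplingResult", "zero_lag_xcorr", "categorize", "coupling_trial"]

WINDOWS = {"W1": (0, 51), "W2": (50, 101)}  # sample slices of the 101-node base
PAIRINGS = ("MoS_Ankle", "MoS_Hip")


@dataclass(frozen=True)
class CouplingResult:
    pairing: str   # "MoS_Ankle" or "MoS_Hip"
    window: str    # "W1" (0-0.5 s) or "W2" (0.5-1 s)
    r: float       # signed zero-lag correlation
    trial_id: str = ""

    @property
    def r_abs(self) -> float:
        return abs(self.r)

    @property
    def category(self) -> str:
        return categorize(self.r_abs)


def zero_lag_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two windowed, mean-removed series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise AlignmentError("inputs must be equal-length 1-D vectors, n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateError("zero-variance input; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def categorize(r_abs: float) -> str:
    """Strength class of an absolute correlation: boundaries to the upper class."""
    if not 0 <= r_abs <= 1 + 1e-12:
        raise DegenerateError(f"|r| must lie in [0, 1], got {r_abs}")
    if r_abs >= 0.5:
        return "strong"
    if r_abs >= 0.3:
        return "moderate"
    return "weak"


def coupling_trial(
    mos_series: MosSeries,
    torques: TorqueSeries,
    trial_id: str = "",
) -> list[CouplingResult]:
    """Four coupling outcomes (2 pairings x 2 windows) for one trial.

    The 101-sample window base splits as 51 + 51 with the 0.5-s boundary
    sample shared by both windows.
    """
    m = mos_series.mos.samples
    taus = {"MoS_Ankle": torques.ankle_frontal.samples,
            "MoS_Hip": torques.hip_frontal.samples}
    n = m.size
    for name, tau in taus.items():
        if tau.size != n:
            raise AlignmentError(f"{name}: torque length {tau.size} != MoS length {n}")
    mid = (n - 1) // 2
    windows = {"W1": (0, mid + 1), "W2": (mid, n)}
    results = []
    for pairing in PAIRINGS:
        tau = taus[pairing]
        for win, (i0, i1) in windows.items():
            r = zero_lag_xcorr(m[i0:i1], tau[i0:i1])
            results.append(CouplingResult(pairing=pairing, window=win, r=r,
                                          trial_id=trial_id))
    return results
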