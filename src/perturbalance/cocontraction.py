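"""Co-contraction index (CCI) for the TA-PL and TA-SOL muscle pairs.

The index is twice the mean pointwise ratio of the smaller to the summed
agonist/antagonist envelope samples over the 1-s perturbation window,
expressed in percent:

    CCI = (2 / n) * sum_i  min(ag_i, ant_i) / (ag_i + ant_i)  * 100

It is 100 exactly when the two envelopes coincide at every counted sample
and 0 when they never overlap. Samples where both envelopes are (numerically)
zero carry no co-contraction information and are excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .errors import AlignmentError, DataError, DegenerateError

__all__ = ["CCIResult", "cci", "cci_trial"]

ZERO_SUM_EPS = 1e-12

MUSCLE_PAIRS = {"TA_PL": ("TA", "PL"), "TA_SOL": ("TA", "SOL")}


@dataclass(frozen=True)
class CCIResult:
    pair: str            # "TA_PL" or "TA_SOL"
    value: float         # percent
    trial_id: str = ""
    window: tuple[float, float] = (0.0, 1.0)  # s


def cci(ag: np.ndarray, ant: np.ndarray, eps: float = ZERO_SUM_EPS) -> float:
    """Co-contraction index in percent for two non-negative envelope vectors."""
    ag = np.asarray(ag, dtype=float)
    ant = np.asarray(ant, dtype=float)
    if ag.shape != ant.shape or ag.ndim != 1 or ag.size < 1:
        raise AlignmentError("envelopes must be equal-length 1-D vectors")
    if np.any(ag < 0) or np.any(ant < 0):
        raise DataError("envelope samples must be non-negative")
    total = ag + ant
    valid = total > eps
    if not valid.any():
        raise DegenerateError("all samples have zero envelope sum")
    ratio = np.minimum(ag[valid], ant[valid]) / total[valid]
    return float(2.0 * ratio.mean() * 100.0)


def cci_trial(
    envelopes: dict[str, TimeSeries],
    window: tuple[float, float] = (0.0, 1.0),
    trial_id: str = "",
) -> tuple[CCIResult, CCIResult]:
    """CCI for TA-PL and TA-SOL over the perturbation window.

    ``envelopes`` maps muscle names (TA, PL, SOL) to normalized envelopes
    already on the common window base (t0 = 0); ``window`` selects the
    sub-span in seconds.
    """
    missing = [m for m in ("TA", "PL", "SOL") if m not in envelopes]
    if missing:
        raise DataError(f"missing muscle envelope(s): {missing}")
    results = []
    for pair, (ant, ag) in MUSCLE_PAIRS.items():
        a = envelopes[ag].slice(*window).samples
        b = envelopes[ant].slice(*window).samples
        results.append(CCIResult(pair=pair, value=cci(a, b),
                                 trial_id=trial_id, window=window))
    return results[0], results[1]
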