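"""Exception hierarchy for the perturbalance pipeline."""


class PerturbalanceError(Exception):
    """Base class for all package errors."""


class ConfigError(PerturbalanceError):
    """Invalid simulation or run configuration."""


class DataError(PerturbalanceError):
    """Non-finite or otherwise unusable input samples."""


class SamplingRateError(PerturbalanceError):
    """A channel's sampling rate violates a processing precondition."""


class SyncError(PerturbalanceError):
    """Perturbation-onset detection failed (fewer bursts than expected)."""


class AlignmentError(PerturbalanceError):
    """Waveforms expected on a shared time base do not align."""


class BoundsError(PerturbalanceError):
    """Requested window exceeds the recorded span."""


class DegenerateError(PerturbalanceError):
    """Degenerate input (zero variance, zero envelope, zero baseline RMS)."""


class ModelError(PerturbalanceError):
    """Inconsistent or incomplete body-model specification."""


class ContactError(PerturbalanceError):
    """Vertical ground reaction force non-positive (loss of plate contact)."""


class DesignError(PerturbalanceError):
    """Statistical design unusable as given (e.g. unbalanced two-way RM design)."""
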