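"""Exception hierarchy for survgain.

All package errors derive from :class:`SurvGainError` so callers (and the
CLI) can distinguish data/usage problems from programming bugs.
"""


class SurvGainError(Exception):
    """Base class for all survgain errors."""


class ConfigError(SurvGainError):
    """Invalid configuration: unknown keys, out-of-range values."""


class DataError(SurvGainError):
    """Malformed input data: bad cohort schema, impossible shapes."""


class CalibrationError(SurvGainError):
    """Intercept calibration failed (no bracket within the search interval)."""


class PSFitError(SurvGainError):
    """Propensity-model fit failed (separation, non-convergence, single-class).

    Carries the optimizer diagnostics, when available, in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MatchingError(SurvGainError):
    """Matching could not be performed (too few controls, bootstrap refit failures)."""
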