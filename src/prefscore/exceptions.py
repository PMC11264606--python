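"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`PrefscoreError`
so callers can catch one type at the CLI boundary.
"""


class PrefscoreError(Exception):
    """Base class for all errors raised by prefscore."""


class ValidationError(PrefscoreError, ValueError):
    """Invalid input data (out-of-range level, missing domain, bad shape)."""


class ConfigurationError(PrefscoreError):
    """A value-set / scoring specification file is malformed or incomplete."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns; lists every offender."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"missing required columns: {', '.join(self.missing)}")


class InsufficientDataError(PrefscoreError):
    """Too few complete cases for the requested statistic."""


class UndefinedStatisticError(PrefscoreError):
    """The statistic is undefined for this input (zero variance, degenerate denominator)."""


class DegenerateFitError(PrefscoreError):
    """A regression fit is degenerate (zero predictor variance)."""


class RankDeficiencyError(DegenerateFitError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design; offending columns: {', '.join(self.columns)}")


class FitFailureError(PrefscoreError):
    """An iterative fit failed to converge; carries the optimizer message."""


class CalibrationError(PrefscoreError):
    """Synthetic-cohort moment calibration failed; carries residuals when known."""

    def __init__(self, message, residuals=None):
        self.residuals = residuals
        super().__init__(message)
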