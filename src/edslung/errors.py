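"""Exception hierarchy for the expert diagnostic system."""


class EdsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EdsError):
    """A configuration value (weight table, bounds, rule base, ...) is invalid."""


class DataValidationError(EdsError):
    """A patient record or input file failed validation."""


class MeasurementError(EdsError):
    """A physiologically impossible spirometry value was supplied."""


class DivergenceError(EdsError):
    """Network training produced a non-finite loss."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class UndefinedMetricError(EdsError):
    """A requested statistic has a zero denominator and is undefined."""


class RejectionLimitError(EdsError):
    """Rejection sampling could not satisfy the cohort spec constraints."""
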