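"""Exception hierarchy for the gait-analysis pipeline."""


class ZuptGaitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ZuptGaitError):
    """Input file does not conform to the expected layout."""


class ParseError(ZuptGaitError):
    """A cell or field could not be parsed."""


class ConfigurationError(ZuptGaitError):
    """Invalid or missing configuration value / metadata."""


class SpecError(ZuptGaitError):
    """Invalid simulation or parameter specification."""


class InsufficientDataError(ZuptGaitError):
    """Not enough samples to perform the requested operation."""


class NotApplicableError(ZuptGaitError):
    """Operation does not apply to this recording (e.g. no timestamps)."""


class InitializationError(ZuptGaitError):
    """Filter could not be initialized (no initial rest period)."""


class DataLossError(ZuptGaitError):
    """Recording has gaps too large to process.

    Carries the offending gap intervals in ``gap_intervals``.
    """

    def __init__(self, message, gap_intervals=None):
        super().__init__(message)
        self.gap_intervals = list(gap_intervals or [])


class NumericalStateError(ZuptGaitError):
    """Filter state became numerically invalid (non-PSD covariance, singular innovation)."""


class NoGaitError(ZuptGaitError):
    """No gait events could be detected."""


class DegenerateClusterError(ZuptGaitError):
    """Clustering input is degenerate (all values identical)."""
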