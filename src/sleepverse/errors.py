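class SleepverseError(Exception):
    """Base class for package errors."""


class ConfigurationError(SleepverseError):
    """Invalid simulation or analysis configuration; names the offending field."""


class FormatError(SleepverseError):
    """Malformed input file; carries a line number when one is known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegeneratePredictorError(SleepverseError):
    """Raised when a model fit is refused because the predictor is constant."""
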