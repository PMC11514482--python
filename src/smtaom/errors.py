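"""Exception hierarchy shared across the package."""


class SmtaomError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SmtaomError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(SmtaomError):
    """A domain object violates one of its invariants."""


class GenerationError(SmtaomError):
    """Synthetic data could not be generated under the requested settings."""


class AlignmentError(SmtaomError):
    """An alignment was requested on a degenerate input."""


class CalibrationError(SmtaomError):
    """Telomere-length calibration inputs are insufficient."""


class SummaryError(SmtaomError):
    """Cohort statistics were requested on an empty or degenerate call set."""


class ConfigError(SmtaomError):
    """A pipeline configuration is invalid."""
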