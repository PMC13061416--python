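"""Exception hierarchy for the larvasleep pipeline.

All pipeline errors derive from :class:`LarvaSleepError` so that callers (and
the CLI) can distinguish pipeline failures from programming errors.
"""


class LarvaSleepError(Exception):
    """Base class for all larvasleep errors."""


class InvalidParameterError(LarvaSleepError, ValueError):
    """A parameter violates a documented precondition."""


class ConfigError(LarvaSleepError):
    """A run configuration is missing or inconsistent."""


class FormatError(LarvaSleepError):
    """An input file violates the expected on-disk format."""


class ParseError(FormatError):
    """A text record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class OrderingError(FormatError):
    """Timestamps or indices are not in the required order/spacing."""


class DegenerateInputError(LarvaSleepError, ValueError):
    """Input carries no usable signal (e.g. all scores identical)."""


class EmptyWellError(LarvaSleepError):
    """No animal could be detected anywhere in a well's frame stack."""


class InvalidROIError(LarvaSleepError, ValueError):
    """A cell ROI does not support the requested quantification."""


class BodyNotFoundError(LarvaSleepError):
    """No larval body could be segmented in an image."""
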