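"""Exception hierarchy.

The engine distinguishes *retryable* I/O failures (an unreachable or
transiently unavailable data source) from permanent ones (malformed input,
invalid specifications), because the two get different treatment at the
task level: retryable errors earn one automatic retry, everything else
fails the task immediately.
"""


class BamsiftError(Exception):
    """Base class for all package errors."""


class ValidationError(BamsiftError, ValueError):
    """A specification, record or parameter violates its contract."""


class SourceUnavailableError(BamsiftError, IOError):
    """The data source could not be reached or read; retry may help."""


class MalformedInputError(BamsiftError, ValueError):
    """The input was reached but could not be parsed; retry will not help."""


class IafParseError(MalformedInputError):
    """A line of individual-alignment-format text is malformed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class UnknownJobError(BamsiftError, KeyError):
    """A job id was not found in the engine's registry."""
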