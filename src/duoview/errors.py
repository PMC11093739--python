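"""Exception hierarchy for the duoview toolkit."""


class DuoviewError(Exception):
    """Base class for all duoview errors."""


class ValidationError(DuoviewError, ValueError):
    """An input violates a documented precondition."""


class SchemaError(ValidationError):
    """A tabular input is missing or duplicating required columns/rows."""


class FormatError(DuoviewError):
    """A file exists but does not hold the expected content."""


class IOFailure(DuoviewError, OSError):
    """A file could not be read or written; the message names the path."""


class ConvergenceError(DuoviewError):
    """An iterative fit or registration failed to converge."""


class GenerationError(DuoviewError):
    """A synthetic phantom could not be generated under its constraints."""


class EmptyResultError(DuoviewError):
    """An operation that requires detections found none."""
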