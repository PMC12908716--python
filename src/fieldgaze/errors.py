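"""Exception hierarchy for the fieldgaze pipeline.

Every stage raises a subclass of :class:`FieldgazeError` so callers (and the
session orchestrator) can catch pipeline failures without masking genuine
programming errors.
"""


class FieldgazeError(Exception):
    """Base class for all fieldgaze errors."""


class FormatError(FieldgazeError):
    """A file or table violates the expected format (e.g. missing column)."""


class OrderingError(FieldgazeError):
    """Timestamps are not strictly increasing."""


class RangeError(FieldgazeError):
    """A value lies outside its documented domain."""


class ParameterError(FieldgazeError):
    """An operation was called with an invalid parameter."""


class EmptyInputError(FieldgazeError):
    """An input that must be non-empty is empty."""


class CoverageError(FieldgazeError):
    """A required group (target, window, ...) has no usable samples."""


class DegenerateInputError(FieldgazeError):
    """Input is formally valid but the operation is undefined on it."""


class IllConditionedError(FieldgazeError):
    """The data cannot support the requested estimate (e.g. motionless GPS)."""


class UndefinedBearingError(FieldgazeError):
    """Bearing requested between coincident points."""
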