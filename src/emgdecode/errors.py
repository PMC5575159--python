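"""Exception hierarchy for the decoding pipeline.

Every contract violation raises a subclass of :class:`DecodeError` so callers
(and the CLI) can distinguish pipeline errors from programming errors.
"""


class DecodeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DecodeError):
    """A file does not match the expected column/dataset layout."""


class SamplingError(DecodeError):
    """The time base of a recording is unusable (non-uniform, too short)."""


class DataError(DecodeError):
    """Values in a recording violate an invariant (NaN cells, empty trial)."""


class AlignmentError(DecodeError):
    """Trigger-based stream alignment is impossible."""


class ParameterError(DecodeError):
    """A processing parameter is outside its valid domain."""


class InputError(DecodeError):
    """An in-memory input violates an operation's precondition."""


class TrainingError(DecodeError):
    """Training cannot proceed (e.g. not enough data for the parameter count)."""


class NumericalError(DecodeError):
    """A numerical failure (non-finite loss) occurred during optimization."""


class UndefinedMetricError(DecodeError):
    """A performance metric is undefined for the given signals."""


class PartitionError(DecodeError):
    """A cross-validation partition cannot be constructed."""
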