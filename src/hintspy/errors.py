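"""Exception hierarchy shared across the package."""


class HintsError(Exception):
    """Base class for all package errors."""


class RecordingFormatError(HintsError):
    """A recording file does not match the expected CSV dialect."""


class EmptyRecordingError(HintsError):
    """An operation would produce or consume a recording with no frames."""


class InsufficientDataError(HintsError):
    """Too few valid samples for the requested computation."""


class DataError(HintsError):
    """Numerically invalid data (non-monotone time, zero intervals, ...)."""


class AlignmentError(HintsError):
    """Two series that must share a time base do not."""


class ConflictError(HintsError):
    """Conflicting inputs, e.g. duplicate stage files for one subject."""


class ContractError(HintsError):
    """An argument violates a documented contract (wrong units, ...)."""


class ParameterError(HintsError):
    """A parameter value is outside its admissible range."""
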