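"""Exception hierarchy shared by all pipeline stages."""


class OscipainError(Exception):
    """Base class for all package errors."""


class FormatError(OscipainError):
    """A file does not conform to its declared format (names the offending field)."""


class LabeledChannelError(OscipainError):
    """A required channel label (e.g. a mastoid) is missing or unknown."""


class ValidationError(OscipainError):
    """Metadata or domain-object invariant violated."""


class ParameterError(OscipainError):
    """A parameter is outside the range an operation supports."""


class StatisticsError(OscipainError):
    """A statistical routine received degenerate input (group too small, zero marginal...)."""


class DecompositionError(OscipainError):
    """ICA could not be computed (e.g. rank-deficient data)."""


class FitError(OscipainError):
    """A model fit failed (e.g. a class absent from the training data)."""


class FoldError(OscipainError):
    """A cross-validation fold is invalid; carries the offending subject id."""


class ConsistencyError(OscipainError):
    """Objects that must share a grid/channel list do not."""


class EmptyResultError(OscipainError):
    """An operation removed everything (e.g. all epochs rejected)."""
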