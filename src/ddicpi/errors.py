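"""Exception hierarchy for ddicpi.

Every error raised by the library derives from :class:`DdicpiError` so callers
(and the CLI) can catch the whole family at one place.
"""


class DdicpiError(Exception):
    """Base class for all ddicpi errors."""


class ParseError(DdicpiError):
    """A file could not be parsed; the message names the offending location."""


class DuplicateIdentifierError(ParseError):
    """A drug or target identifier appears more than once in one table."""


class UnknownIdentifierError(DdicpiError):
    """A drug or target identifier is not declared in the panel/library."""


class PanelMismatchError(DdicpiError):
    """Feature vectors or score rows do not share the same target panel."""


class MissingDataError(DdicpiError):
    """An operation touched a missing (NA) docking score."""


class UnparseableResultError(ParseError):
    """A docking-result file contains no affinity information."""


class CapacityError(DdicpiError):
    """A sampling request exceeds the number of available candidates."""


class DegenerateLabelsError(DdicpiError):
    """Training or a metric needs both classes but only one is present."""


class UndefinedMetricError(DdicpiError):
    """A metric is undefined for the given labels (e.g. single class)."""


class ValidationError(DdicpiError):
    """Inputs violate a documented precondition (non-finite values, bad shapes)."""


class ModelFileError(ParseError):
    """A model file is corrupted, truncated, or has an unsupported version."""
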