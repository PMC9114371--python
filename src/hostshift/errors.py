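"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, DataValidationError (and
subclasses) to 3, anything else to 4.
"""


class HostShiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HostShiftError):
    """Bad run configuration (missing paths, invalid parameter combinations)."""


class DataValidationError(HostShiftError):
    """Input data violates a documented precondition."""


class AlignmentShapeError(DataValidationError):
    """Sequences in one alignment have unequal lengths."""


class DuplicateIdError(DataValidationError):
    """The same sequence identifier occurs more than once."""


class EmptyInputError(DataValidationError):
    """An operation received no usable input."""


class LabelMismatchError(DataValidationError):
    """Two trees (or a tree and a map) disagree on their leaf label sets."""


class NewickError(DataValidationError):
    """Malformed Newick text."""


class CalibrationError(DataValidationError):
    """Clock calibration impossible (e.g. all host divergences zero)."""
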