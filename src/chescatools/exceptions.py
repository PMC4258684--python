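"""Exception hierarchy shared across the tool set."""


class ChescaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChescaError):
    """A table or file does not have the expected layout (missing columns...)."""


class ParseError(ChescaError):
    """A value in an otherwise well-formed table could not be parsed."""


class ValidationError(ChescaError):
    """Parsed data violates a dataset invariant (duplicates, metadata...)."""


class DegenerateInputError(ChescaError):
    """Input is too small or too uniform for the requested operation."""


class MetadataError(ChescaError):
    """State metadata (activity classes) is missing or inconsistent."""


class CalibrationError(ChescaError):
    """A synthetic fixture failed its own construction-time constraints."""
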