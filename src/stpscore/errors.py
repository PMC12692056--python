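"""Exception hierarchy shared across the package.

Validation errors map to CLI exit code 1, I/O errors to exit code 2.
"""


class StpscoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StpscoreError):
    """Structurally invalid input file (duplicate ids, bad columns...)."""


class ParseError(FormatError):
    """A cell or field could not be parsed; message carries row/column context."""


class ValidationError(StpscoreError):
    """Input violates a documented precondition or invariant."""


class ParameterError(ValidationError):
    """Model parameter outside its admissible range."""
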