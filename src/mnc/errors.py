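"""Exception hierarchy.

``MncError`` is the base; the CLI maps ``InputError`` subclasses to exit
code 2 and ``NumericalError`` subclasses to exit code 1.
"""


class MncError(Exception):
    """Base class for all package errors."""


class InputError(MncError):
    """User-supplied data or configuration is malformed."""


class FormatError(InputError):
    """A file does not have the expected layout (missing columns, empty)."""


class ParseError(InputError):
    """A value could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class IntegrityError(InputError):
    """Structural invariant violated (duplicate triples, bad coding)."""


class ConfigError(InputError):
    """Invalid simulation or run configuration."""


class NumericalError(MncError):
    """Numerical failure (singular covariance, undefined degrees of freedom)."""


class EstimabilityError(NumericalError):
    """A covariance element cannot be estimated from the observed design."""
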