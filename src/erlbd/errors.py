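"""Exception hierarchy.

Exit codes used by the command-line layer: 2 configuration problems,
3 data/validation problems, 4 numerical degeneracies.
"""


class ErlbdError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ErlbdError):
    """Bad option, unknown key, or inconsistent combination of inputs."""

    exit_code = 2


class ValidationError(ErlbdError):
    """Input data fails a precondition."""

    exit_code = 3


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


class EmptyStructureError(ParseError):
    """A structure source contained no usable atom records."""


class EmptySelectionError(ValidationError):
    """An atom selection matched nothing."""


class InsufficientDataError(ValidationError):
    """Too few points/pairs for the requested computation."""


class DegeneracyError(ErlbdError):
    """Numerically degenerate configuration (collinear points, zero variance)."""

    exit_code = 4
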