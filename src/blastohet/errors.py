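"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration problems (2), malformed
data (3), numerical failures (4).
"""


class BlastohetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(BlastohetError):
    """Invalid parameter combination or pipeline configuration."""

    exit_code = 2


class FormatError(BlastohetError):
    """Malformed on-disk data or violated matrix invariants."""

    exit_code = 3


class AlignmentError(FormatError):
    """Two objects that must share cells/genes do not."""


class NormalizationError(BlastohetError):
    """Size-factor estimation impossible on the given matrix."""

    exit_code = 4


class InsufficientDataError(BlastohetError):
    """Too few cells/genes/pairs for the requested computation."""

    exit_code = 3


class NumericalError(BlastohetError):
    """Iterative procedure failed to converge or produced invalid values."""

    exit_code = 4
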