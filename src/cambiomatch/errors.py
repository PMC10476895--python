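"""Exception hierarchy shared by all cambiomatch modules.

Contract violations (bad inputs, unmet preconditions) raise
:class:`ContractError` subclasses so callers and the CLI can map them to a
single exit code; I/O and format problems raise :class:`FormatError`
subclasses.
"""


class CambiomatchError(Exception):
    """Base class for all package-specific errors."""


class ContractError(CambiomatchError):
    """A documented precondition of an operation was violated."""


class FormatError(CambiomatchError):
    """Input file could not be parsed."""


class IntegrityError(FormatError):
    """Duplicate records with conflicting values."""


class GapError(ContractError):
    """Calendar gaps in a daily series above the configured tolerance."""


class CoverageError(ContractError):
    """A computation requested days/years not covered by the series."""


class ParameterError(ContractError):
    """Invalid parameter vector (ordering, bounds, domain)."""


class DomainError(ContractError):
    """A value lies outside the mathematical domain of a transform."""


class AlignmentError(ContractError):
    """Two year-indexed series do not align."""


class DegenerateInputError(ContractError):
    """Zero-variance or otherwise degenerate statistical input."""


class UndefinedRatioError(ContractError):
    """A ratio of slopes with a (numerically) zero denominator."""


class RankError(ContractError):
    """Rank-deficient (collinear) control matrix."""


class ConfigError(CambiomatchError):
    """Invalid or inconsistent configuration."""
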