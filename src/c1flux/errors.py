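"""Exception hierarchy.

Exit-code mapping used by the CLI: UsageError -> 2, InfeasibleError -> 3,
FitError -> 4; everything else -> 1.
"""


class C1FluxError(Exception):
    """Base class for all package errors."""


class UsageError(C1FluxError):
    """Bad user input: unknown dialect, unknown scenario, bad config."""


class ParseError(C1FluxError):
    """A model file could not be parsed; message names the offending element."""


class CurationError(C1FluxError):
    """A curation edit could not be applied; message names edit and target."""


class InfeasibleError(C1FluxError):
    """The LP is infeasible for the requested model/medium combination."""


class SolverError(C1FluxError):
    """The LP backend failed for a reason other than infeasibility."""


class FitError(C1FluxError):
    """Growth-curve fitting found no acceptable exponential window."""


class CalibrationError(C1FluxError):
    """Assay standards are unusable (non-monotone, too few, zero slope)."""


class DomainError(C1FluxError, ValueError):
    """A numeric argument is outside its mathematical domain."""
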