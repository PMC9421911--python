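"""Exception hierarchy.

All errors raised by the library derive from :class:`FloryFitError`, so
callers (and the CLI) can map failure modes to distinct exit codes.
"""


class FloryFitError(Exception):
    """Base class for all floryfit errors."""


class DomainError(FloryFitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class OnePhaseRegionError(FloryFitError):
    """chi <= chi_c(N): the system is in the one-phase region and no
    coexistence (binodal/spinodal) pair exists."""


class ConvergenceError(FloryFitError):
    """An iterative solver failed to converge to the requested residual."""


class NumericError(FloryFitError):
    """A non-finite intermediate was produced; the message carries the
    iterate context."""


class FormatError(FloryFitError, ValueError):
    """A file or table violates the expected schema; messages include the
    offending line number where possible."""
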