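"""Exception hierarchy shared across the package.

All exceptions derive from :class:`IsgelError` so callers (and the CLI) can
catch package failures with one except clause while still distinguishing
the failure mode.
"""


class IsgelError(Exception):
    """Base class for all package errors."""


class InvalidModelError(IsgelError, ValueError):
    """A release model violates its invariants (non-positive rate or plateau)."""


class DomainError(IsgelError, ValueError):
    """An evaluation time lies outside the model's domain (before t0)."""


class InvalidInputError(IsgelError, ValueError):
    """Input data violate a precondition (e.g. decreasing cumulative release)."""


class ConfigurationError(IsgelError, ValueError):
    """Inconsistent or incomplete configuration (protocol, noise, sphere spec)."""


class GridError(IsgelError, ValueError):
    """A time grid is unusable: non-uniform beyond tolerance, or too coarse."""


class InsufficientDataError(IsgelError, ValueError):
    """Too few samples for the requested stencil or regression."""


class DegenerateDesignError(IsgelError, ValueError):
    """The regression design has no variance (constant response)."""


class NonPhysicalFitError(IsgelError, ValueError):
    """The estimated rate constant is non-positive.

    Carries the raw least-squares estimates so callers can inspect them.
    """

    def __init__(self, message: str, a_hat: float, b_hat: float):
        super().__init__(message)
        self.a_hat = a_hat
        self.b_hat = b_hat


class UndefinedMetricError(IsgelError, ValueError):
    """A goodness-of-fit metric is undefined for the given data."""


class SolverError(IsgelError, RuntimeError):
    """The PDE integrator failed to meet its tolerances."""


class StabilityError(IsgelError, RuntimeError):
    """The PDE solution developed negative concentrations beyond round-off."""
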