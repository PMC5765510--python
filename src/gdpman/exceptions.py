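"""Exception hierarchy for gdpman.

All package errors derive from :class:`GdpmanError` so callers can catch
everything in one clause; the subclasses distinguish user mistakes
(configuration, validation, parsing) from numerical failures (solver,
convergence, internal consistency).
"""


class GdpmanError(Exception):
    """Base class for all gdpman errors."""


class ConfigurationError(GdpmanError, ValueError):
    """An unknown variant, reaction id, stage or option was requested."""


class ValidationError(GdpmanError, ValueError):
    """An input value violates a precondition (negative concentration,
    non-positive rate constant, malformed design, ...)."""


class ParseError(GdpmanError, ValueError):
    """A data or config file could not be parsed; carries row/field context."""


class SolverError(GdpmanError, RuntimeError):
    """ODE integration failed.

    Attributes
    ----------
    last_valid_time : float
        The last time point the integrator reached before failing.
    """

    def __init__(self, message: str, last_valid_time: float = float("nan")):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class ConvergenceError(GdpmanError, RuntimeError):
    """A quantity that requires a converged state (an equilibrium ratio, a
    fit) was requested before convergence; carries the residual."""

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class ConsistencyError(GdpmanError, RuntimeError):
    """An internal invariant (moiety conservation) was violated beyond
    tolerance."""


class FitFailureError(GdpmanError, RuntimeError):
    """No evaluated parameter vector produced a successful simulation."""
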