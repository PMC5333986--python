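"""Exception hierarchy for the gqm package.

All gqm-specific errors derive from :class:`GqmError` so callers can catch
everything the package raises with a single clause; the mixin bases
(``ValueError``, ``KeyError``, ``RuntimeError``) keep the exceptions
idiomatic for code that does not know about gqm.
"""


class GqmError(Exception):
    """Base class for all gqm errors."""


class DomainError(GqmError, ValueError):
    """An argument lies outside its mathematical/physical domain."""


class UndefinedKdError(DomainError):
    """K_D is undefined because the complex concentration is zero."""


class ConfigError(GqmError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class UnknownCloneError(GqmError, KeyError):
    """A clone id is not present in the affinity matrix / repertoire."""


class NoCognateError(GqmError, KeyError):
    """A clone has no finite affinity entry, hence no cognate epitope."""


class SolverError(GqmError, RuntimeError):
    """The equilibrium solver failed to converge.

    Attributes
    ----------
    residual : float
        Largest relative conservation residual at the point of failure.
    """

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class ConsistencyError(GqmError, ValueError):
    """An equilibrium state does not satisfy its conservation invariants."""


class FrozenCloneError(GqmError, ValueError):
    """A long-lived plasma-cell clone rejected an affinity/regulation update."""


class SimulationError(GqmError, RuntimeError):
    """An event in a simulated sequence failed; carries the event index."""

    def __init__(self, message: str, event_index: int):
        super().__init__(message)
        self.event_index = event_index


class RegulationWarning(UserWarning):
    """The regulation controller returned a best-effort, unconverged state."""
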