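"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ParameterError -> 1 (usage),
DataError -> 2, numerical failures (FitError, OptimizationError) -> 3.
"""


class SeqReachError(Exception):
    """Base class for all package errors."""


class ParameterError(SeqReachError, ValueError):
    """An argument violates a documented precondition."""


class DataError(SeqReachError, ValueError):
    """Input data violate a structural requirement (timestamps, schema, ...)."""


class IncompleteTrialError(DataError):
    """A trial never approached one of the sequence waypoints.

    Carries the label of the first missing waypoint so callers can report
    which reach failed.
    """

    def __init__(self, waypoint: str, message: str | None = None):
        self.waypoint = waypoint
        super().__init__(message or f"trial never came within the proximity radius of waypoint {waypoint!r}")


class FitError(SeqReachError, RuntimeError):
    """A least-squares or bootstrap fit could not be completed."""


class OptimizationError(SeqReachError, RuntimeError):
    """Trajectory optimization failed; carries the best iterate found."""

    def __init__(self, message: str, best=None, diagnostics=None):
        self.best = best
        self.diagnostics = diagnostics or {}
        super().__init__(message)
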