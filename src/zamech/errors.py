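"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input object violates its documented contract."""


class IntegrationFailure(RuntimeError):
    """Raised when an ODE integration produces a non-finite state.

    Attributes
    ----------
    time : float
        Model time at which the failure was detected.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class FitError(RuntimeError):
    """Raised when a curve fit cannot be attempted at all (too few points,
    degenerate geometry). Non-convergence of an attempted fit is *not* an
    error: it is reported through the ``converged`` flag of the fit result."""
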