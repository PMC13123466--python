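"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """A physically or structurally invalid input was supplied."""


class SolverError(RuntimeError):
    """The iterative flow solver failed to converge.

    Carries the residual history so the caller can inspect the failure.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class UndefinedMetricError(ValueError):
    """A ratio metric was requested with an empty denominator (e.g. an
    empty top outlet), so the quantity is undefined rather than zero."""
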