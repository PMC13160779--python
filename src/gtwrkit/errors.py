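"""Exception hierarchy shared across the toolkit."""


class GtwrkitError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GtwrkitError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(GtwrkitError, ValueError):
    """Input has no usable variation (e.g. a constant vector)."""


class SingularDesignError(GtwrkitError, ValueError):
    """Design matrix is rank deficient.

    ``columns`` names the offending columns when they could be identified.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class SingularLocalFitError(GtwrkitError, ValueError):
    """A locally weighted design is numerically singular (weights too
    concentrated around one observation)."""

    def __init__(self, message: str, obs_index: int | None = None):
        super().__init__(message)
        self.obs_index = obs_index


class AICcUndefinedError(GtwrkitError, ValueError):
    """Effective degrees of freedom exhausted: n - 2 - tr(S) <= 0."""


class SelectionFailureError(GtwrkitError, RuntimeError):
    """No bandwidth grid point produced a defined AICc."""


class UndefinedOffsetError(GtwrkitError, ValueError):
    """All local coefficients are zero for a predictor; offsets undefined."""
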