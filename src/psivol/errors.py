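"""Exception types shared across the package."""


class PsivolError(Exception):
    """Base class for all package errors."""


class ParameterError(PsivolError, ValueError):
    """An input parameter violates its contract (non-positive scale, bad mixture weight, ...)."""


class PackingError(PsivolError, RuntimeError):
    """Non-overlapping sphere packing could not reach the requested count."""

    def __init__(self, requested: int, achieved: int, max_attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.max_attempts = max_attempts
        super().__init__(
            f"packed {achieved}/{requested} non-overlapping spheres "
            f"within {max_attempts} attempts per sphere; reduce density or count"
        )


class EstimationError(PsivolError, RuntimeError):
    """The estimator received no usable intercepts."""


class DegenerateStatisticError(PsivolError, ValueError):
    """A statistic is undefined on this input (e.g. zero chance-corrected denominator)."""


class ReplicateError(PsivolError, RuntimeError):
    """A replicate measurement failed; carries the failing replicate index."""

    def __init__(self, replicate: int, cause: Exception):
        self.replicate = replicate
        self.cause = cause
        super().__init__(f"replicate {replicate} failed: {cause}")
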