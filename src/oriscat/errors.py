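"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class GridRangeError(ValidationError):
    """Raised when a reciprocal-space query lies outside a grid's q_max."""


class ConvergenceWarningFlag:
    """Sentinel-ish metadata key names for Monte Carlo convergence reporting."""

    CONVERGED = "converged"
    N_SAMPLES = "n_samples"
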