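"""Exception and warning types used across the package."""


class StbssError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StbssError, ValueError):
    """A kernel, covariance-model or matrix parameter is outside its admissible range."""


class EmptyKernelError(StbssError, ValueError):
    """A kernel selects no space-time pairs on the given sample locations."""


class InsufficientDataError(StbssError, ValueError):
    """Fewer complete-case observations than the estimator requires."""


class RankDeficiencyError(StbssError, ValueError):
    """The covariance used for whitening is singular or numerically rank deficient."""


class SizeGuardError(StbssError, ValueError):
    """A dense n x n operation was requested above the configured size guard."""


class ConvergenceWarning(UserWarning):
    """Iterative joint diagonalization stopped at the sweep limit."""


class IdentifiabilityWarning(UserWarning):
    """Near-equal diagonal values: component order/sign may be unstable."""
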