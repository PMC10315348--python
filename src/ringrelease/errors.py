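"""Exception hierarchy shared across the package."""


class RingReleaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RingReleaseError, ValueError):
    """A physical or model parameter is outside its valid domain."""


class InsufficientDataError(RingReleaseError, ValueError):
    """Too few (or degenerate) data points for the requested operation."""


class SingularFitError(RingReleaseError, ValueError):
    """Regression design matrix is singular (e.g. all-equal abscissa)."""


class ScheduleMismatchError(RingReleaseError, ValueError):
    """Measured time points do not line up with the sampling protocol."""


class ValidationError(RingReleaseError, ValueError):
    """Input data violate a structural invariant (negative concentration,
    unsorted times, mixed phases, missing columns, ...)."""


class EmptyInputError(ValidationError):
    """An input file parsed cleanly but contains no data."""


class MassBalanceError(RingReleaseError, RuntimeError):
    """Simulator mass balance drifted beyond tolerance even after step
    refinement; indicates unstable rate parameters for the step size."""
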