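"""Exception types shared across the package."""


class FacePriorsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FacePriorsError, ValueError):
    """An input value violates a documented precondition."""


class FittingError(FacePriorsError, RuntimeError):
    """Model fitting cannot proceed (e.g. a stimulus class is missing)."""


class BoundaryRateError(FacePriorsError, ValueError):
    """Observed hit/false-alarm rate lies on the boundary of (0, 1).

    The closed-form maximum-likelihood solution is undefined there; use the
    bounded numeric fit instead.
    """


class DegenerateDataError(FacePriorsError, ValueError):
    """The data carry no usable variability for the requested statistic."""
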