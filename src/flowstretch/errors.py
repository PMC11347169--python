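"""Exception types shared across the package."""


class FlowstretchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FlowstretchError, ValueError):
    """Invalid input data or parameter value; the message names the field."""


class DegenerateDataError(FlowstretchError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant series)."""


class FitError(FlowstretchError, RuntimeError):
    """A nonlinear fit failed to converge or is ill-posed."""
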