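"""Exception hierarchy used across the pipeline."""


class StromascopeError(ValueError):
    """Base class for all package errors."""


class ParameterError(StromascopeError):
    """Invalid user-supplied parameter or specification."""


class DegenerateInputError(StromascopeError):
    """Input carries no usable signal (constant image, empty sample)."""


class InsufficientDataError(StromascopeError):
    """Too few observations for the requested statistic."""
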