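"""Exception types shared across the package."""


class MitoselectError(Exception):
    """Base class for all package errors."""


class ParameterError(MitoselectError, ValueError):
    """A function argument is outside its valid domain."""


class SchemaError(MitoselectError, ValueError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(MitoselectError, ValueError):
    """A table value violates a range or consistency constraint."""


class EstimationError(MitoselectError, ValueError):
    """An estimator received a degenerate design (e.g. constant regressor)."""


class NormalizationError(MitoselectError, ValueError):
    """The non-competed reference mean is zero at some generation."""


class SaturationError(MitoselectError, ValueError):
    """A ddPCR channel has no negative droplets; its concentration estimate
    is unbounded."""


class ConvergenceError(MitoselectError, RuntimeError):
    """A fixed-point iteration failed to converge within its budget."""
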