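"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (data problems vs optimizer
failures), so library code should raise the most specific type available.
"""


class GWError(Exception):
    """Base class for all gwreg errors."""


class ParameterError(GWError, ValueError):
    """A distribution or model parameter is outside its domain."""


class DataValidationError(GWError, ValueError):
    """Input data violates the model's contract (types, signs, missing columns)."""


class ConvergenceError(GWError, RuntimeError):
    """An optimizer failed and no usable fit could be produced."""


class PartitionUndefinedError(GWError, ValueError):
    """The variance partition was requested where the variance is infinite (rho <= 2)."""
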