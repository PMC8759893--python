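"""Exception hierarchy shared across the toolkit.

The CLI maps :class:`SchemaError` to exit code 2 (bad input / config) and
:class:`NumericalError` to exit code 3 (a computation that could not be
completed on valid input).
"""


class ShearwaveError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(ShearwaveError, ValueError):
    """Malformed input: bad config keys, missing HDF5 datasets, bad CSV."""


class NumericalError(ShearwaveError, RuntimeError):
    """A numerical procedure failed: no valid peaks, non-physical slope,
    non-convergent fit, undefined statistic."""
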