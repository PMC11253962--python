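"""Exception hierarchy shared across the package."""


class BisPkpdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BisPkpdError, ValueError):
    """Malformed or inconsistent input (bad labels, grids, shapes, protocols)."""


class OutOfModelRangeError(BisPkpdError, ValueError):
    """Covariates outside the envelope where the PK model yields positive parameters."""


class UndefinedMetricError(BisPkpdError, ZeroDivisionError):
    """A fit metric is mathematically undefined for the given data
    (constant observations for R-squared, zero observations for MAPE)."""
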