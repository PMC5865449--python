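"""Package-wide exception types."""


class TwinOverlapError(Exception):
    """Base class for all package errors."""


class CalibrationError(TwinOverlapError):
    """A requested margin or correlation target is jointly infeasible."""


class SchemaError(TwinOverlapError):
    """A cohort table is missing mandatory columns or violates invariants."""


class UndefinedCorrelationError(TwinOverlapError):
    """A correlation is requested on a zero-variance variable."""


class FitError(TwinOverlapError):
    """Model fitting failed (non-convergence, invalid input moments)."""
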