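"""Exception hierarchy used across the package.

Every error raised on bad user input derives from :class:`SicstratError`,
so callers can catch one base class at a pipeline boundary.
"""


class SicstratError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SicstratError):
    """A required column is missing or a column mapping is invalid."""


class ValidationError(SicstratError):
    """A record or configuration violates a domain invariant."""


class ParseError(SicstratError):
    """A cell could not be parsed into the expected type."""


class DegenerateDataError(SicstratError):
    """Input lacks the variation an estimator needs (e.g. one outcome class)."""


class ConvergenceError(SicstratError):
    """An iterative fit failed to converge (e.g. perfect separation)."""


class CalibrationError(SicstratError):
    """The synthetic-link calibration could not reach its target."""
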