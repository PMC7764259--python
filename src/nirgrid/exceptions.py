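"""Exception hierarchy for nirgrid.

All package errors derive from :class:`NirGridError` so callers can catch one
base class; subclasses distinguish schema, parse, integrity, parameter, range,
fit and pipeline failures.
"""


class NirGridError(Exception):
    """Base class for all nirgrid errors."""


class SchemaError(NirGridError):
    """A required metadata column is missing or a config field is invalid."""


class ParseError(NirGridError):
    """A value in an input file could not be parsed (carries the row index)."""


class IntegrityError(NirGridError):
    """A structural invariant of the data is violated (e.g. one sample with
    two class labels, a non-monotone wavenumber axis, missing intensities)."""


class ParameterError(NirGridError, ValueError):
    """An operator parameter is out of its valid domain."""


class RangeError(NirGridError, ValueError):
    """A requested wavenumber segment lies outside the axis range."""


class DegenerateFitError(NirGridError):
    """A least-squares fit is numerically degenerate (e.g. MSC slope ~ 0)."""


class FitError(NirGridError):
    """A model could not be fitted (singular covariance, class too small)."""


class PipelineError(NirGridError):
    """A pre-processing pipeline produced an invalid intermediate result."""


class ConfigError(NirGridError):
    """A run or grid configuration is inconsistent."""
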