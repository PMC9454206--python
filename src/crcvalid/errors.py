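"""Exception hierarchy shared across the package.

All errors derive from :class:`CrcValidError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration problems from data problems (the CLI maps these onto distinct
exit codes).
"""


class CrcValidError(Exception):
    """Base class for all package errors."""


class SpecParseError(CrcValidError):
    """A model-spec file could not be parsed; names the offending field."""


class SpecValidationError(CrcValidError):
    """A parsed model spec violates a structural invariant."""


class SchemaError(CrcValidError):
    """Input table does not conform to the cohort schema."""


class EvaluationError(CrcValidError):
    """A record's value falls outside a variable's declared domain."""


class DegenerateInputError(CrcValidError):
    """A statistic was requested on input that cannot support it
    (e.g. single-class labels, no usable pairs, empty group)."""


class PointRangeError(CrcValidError):
    """A point total falls outside the coverage of a risk table."""


class ConfigurationError(CrcValidError):
    """A run configuration value is invalid."""


class DomainError(CrcValidError):
    """A numeric argument lies outside its mathematical domain."""
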