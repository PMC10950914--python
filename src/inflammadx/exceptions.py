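"""Exception hierarchy for inflammadx.

All package errors derive from :class:`InflammadxError` so callers can
catch one base class; the CLI maps subclasses onto exit codes.
"""


class InflammadxError(Exception):
    """Base class for all inflammadx errors."""


class SchemaError(InflammadxError):
    """Input does not conform to the 18-feature schema (missing/renamed columns)."""


class ValidationError(InflammadxError):
    """Values violate cohort invariants (non-numeric, NaN/Inf, out of range)."""


class LabelError(ValidationError):
    """A diagnosis label outside the closed 4-label vocabulary."""


class ConfigError(InflammadxError):
    """Invalid generator / model configuration."""


class SelectionError(InflammadxError):
    """Rule selection impossible (e.g. no rule predicts the positive class)."""


class MetricError(InflammadxError):
    """A metric is undefined for the given counts (empty denominator)."""
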