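"""Exception types shared across the package."""


class ReportMatchError(Exception):
    """Base class for all package errors."""


class SchemaError(ReportMatchError):
    """A serialized record or file does not conform to the expected schema."""


class ConfigurationError(ReportMatchError):
    """Inconsistent or invalid configuration (e.g. dimension mismatches)."""


class GenerationError(ReportMatchError):
    """The synthetic generator cannot satisfy its planting constraints."""


class UndefinedMetricError(ReportMatchError):
    """A metric is undefined for the given input (e.g. AUC on one class)."""
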