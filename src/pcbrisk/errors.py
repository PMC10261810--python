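"""Exception hierarchy for the package."""


class PcbRiskError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PcbRiskError, ValueError):
    """An argument violates a numeric precondition (e.g. non-positive mean)."""


class ConfigError(PcbRiskError, ValueError):
    """A configuration value or distribution specification is invalid."""


class GenerationError(PcbRiskError, RuntimeError):
    """Synthetic-data generation cannot proceed (e.g. infeasible bounds)."""


class SchemaError(PcbRiskError, ValueError):
    """Tabular input does not conform to the expected schema."""


class DataError(PcbRiskError, ValueError):
    """Data values are invalid for the requested operation."""


class InsufficientDataError(PcbRiskError, ValueError):
    """Too few observations for the requested statistic."""
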