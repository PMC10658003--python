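"""Exception hierarchy shared across the package."""


class ConvosyncError(Exception):
    """Base class for all convosync errors."""


class ParseError(ConvosyncError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ConvosyncError):
    """A domain object violates one of its invariants."""


class SchemaError(ConvosyncError):
    """A tabular file does not match the expected column schema."""


class ConfigError(ConvosyncError):
    """Invalid configuration value."""


class UndefinedStatisticError(ConvosyncError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
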