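"""Exception hierarchy shared across the package."""


class StagedRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(StagedRiskError, ValueError):
    """A configuration field is invalid; the message names the field."""


class DataError(StagedRiskError, ValueError):
    """Input data violates a precondition (missing values, single class, ...)."""


class SchemaError(StagedRiskError, ValueError):
    """Feature columns do not match what a fitted object was trained on."""


class CapabilityError(StagedRiskError, TypeError):
    """A base learner lacks a required capability (e.g. importances)."""
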