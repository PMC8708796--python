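"""Exception types shared across the pipeline."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PvSignalError):
    """A configuration value is invalid; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(PvSignalError):
    """A table does not conform to its declared schema."""


class EncodingError(PvSignalError):
    """A file could not be decoded under the declared encoding."""


class UndefinedComparisonError(PvSignalError):
    """A group comparison is undefined (e.g. one group empty after exclusions)."""


class ConstantColumnError(PvSignalError):
    """A matrix column has zero variance and cannot enter correlation PCA."""
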