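"""Exception hierarchy for the dyadsync pipeline."""


class DyadsyncError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DyadsyncError):
    """Invalid generator, model or pipeline configuration."""


class DataError(DyadsyncError):
    """Malformed or incomplete input data (identifies dyad/participant/channel)."""


class QualityError(DyadsyncError):
    """Signal quality too poor for the requested computation (e.g. < 2 peaks)."""


class SchemaError(DyadsyncError):
    """Delimited-text table does not match the expected column schema."""
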