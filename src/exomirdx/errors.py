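"""Exception hierarchy shared across the pipeline stages."""


class ExomirdxError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ExomirdxError, ValueError):
    """A parameter or input value is outside its valid domain."""


class MissingDataError(ExomirdxError):
    """Required measurements are absent (e.g. empty replicate set)."""


class UndefinedMetricError(ExomirdxError):
    """A metric cannot be computed from the given data (e.g. one class absent)."""


class ConfigurationError(ExomirdxError):
    """The run configuration is inconsistent with the data."""
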