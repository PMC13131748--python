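"""Exception types shared across the pipeline stages."""


class IcudcaError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleSpecError(IcudcaError):
    """A cohort specification whose targets cannot be realized."""


class MalformedAdmissionError(IcudcaError):
    """Patient-day rows violate the within-admission structure contract."""


class SchemaMismatchError(IcudcaError):
    """A table does not carry the columns a fitted object was trained on."""


class UndefinedMetricError(IcudcaError):
    """A metric is undefined for the given input (e.g. single-class labels)."""


class ConfigurationError(IcudcaError):
    """A required configuration value is missing or invalid."""


class StageDependencyError(IcudcaError):
    """A pipeline stage was invoked before its upstream artifact exists."""
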