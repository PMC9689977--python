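"""Exception hierarchy shared across the pipeline."""


class GlottiswtError(Exception):
    """Base class for all package errors."""


class ConfigError(GlottiswtError):
    """Invalid configuration value or experiment specification."""


class ParameterError(GlottiswtError):
    """A model parameter lies outside its admissible domain."""


class DegenerateInputError(GlottiswtError):
    """Input is formally valid but carries no usable information (e.g. silence)."""


class StabilityError(GlottiswtError):
    """A requested filter has poles on or outside the unit circle."""


class SchemaError(GlottiswtError):
    """Tabular inputs whose columns do not line up."""


class ConsistencyError(GlottiswtError):
    """Mismatched objects passed to an operation (e.g. wrong wavelet for a sub-band set)."""
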