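"""Exception types shared across the pipeline stages."""


class RiisdegError(Exception):
    """Base class for all package errors."""


class ValidationError(RiisdegError):
    """Input data violates a structural contract (ids, signs, shapes)."""


class ConfigurationError(RiisdegError):
    """A configuration value is out of range or internally inconsistent."""


class GenerationError(RiisdegError):
    """The synthetic-data generator produced or was asked for invalid output."""
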