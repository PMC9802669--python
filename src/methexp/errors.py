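"""Exception hierarchy shared across the pipeline."""


class MethexpError(Exception):
    """Base class for all package errors."""


class ConfigError(MethexpError):
    """Invalid configuration value or malformed config file."""


class MissingInputError(MethexpError):
    """A required input file or prerequisite stage output is absent."""


class ValidationError(MethexpError):
    """Input data violates a documented precondition."""
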