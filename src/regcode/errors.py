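"""Exception hierarchy shared across the package."""


class RegcodeError(Exception):
    """Base class for all package errors."""


class ValidationError(RegcodeError):
    """An input record or configuration object violates its schema."""


class EmptyInputError(RegcodeError):
    """An operation received an empty input it cannot act on."""


class ConfigError(RegcodeError):
    """A generator or run configuration is internally inconsistent."""
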