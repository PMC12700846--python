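"""Shared exception types."""


class GLCSAError(Exception):
    """Base class for package errors."""


class FormatError(GLCSAError):
    """Unreadable or unsupported file format."""


class ValidationError(GLCSAError):
    """Data violates a documented invariant (e.g. unexpected mask labels)."""


class SizeError(GLCSAError):
    """Requested geometry does not fit the data."""


class ConfigError(GLCSAError):
    """Inconsistent or invalid configuration."""


class SchemaError(ConfigError):
    """Configuration file contains unknown or ill-typed keys."""
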