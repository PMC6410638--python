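"""Exception hierarchy shared across the package."""


class EndopanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EndopanelError):
    """A record violates its schema; the message names the offending field."""


class ConfigurationError(EndopanelError):
    """A configuration value is out of range or inconsistent."""


class SchemaError(EndopanelError):
    """A file does not match the expected tabular schema."""
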