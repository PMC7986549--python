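"""Exception hierarchy shared across the package."""


class AutovaError(Exception):
    """Base class for all package errors."""


class ValidationError(AutovaError):
    """Input data violates a domain invariant (bad age, duplicate id, ...)."""


class SchemaError(AutovaError):
    """A file does not match the expected column / field layout."""


class ConfigurationError(AutovaError):
    """Configuration is internally inconsistent (missing cause, bad bins, ...)."""
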