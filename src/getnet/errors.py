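"""Exception types shared across the package."""


class GetnetError(Exception):
    """Base class for all package errors."""


class ValidationError(GetnetError, ValueError):
    """Input data violates a documented precondition or invariant."""


class ConfigurationError(GetnetError, ValueError):
    """A configuration value is inconsistent (shapes, divisibility, heads)."""
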