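"""Exception hierarchy."""


class CminetError(Exception):
    """Base class for all package errors."""


class ValidationError(CminetError, ValueError):
    """Input data violates a documented invariant (shape, labels, values)."""


class ConfigurationError(CminetError, ValueError):
    """A run or generator parameter is out of its valid range."""
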