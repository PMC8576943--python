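"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class ValidationError(ValueError):
    """Raised when an input table or matrix violates its invariants."""
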