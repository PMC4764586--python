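"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Raised when simulation or analysis parameters are invalid."""


class FitError(RuntimeError):
    """Raised when a model fit fails to converge."""
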