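"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid model, phantom or training configuration."""


class ShapeError(ValueError):
    """An input whose shape violates a contract (e.g. not divisible by 32)."""
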