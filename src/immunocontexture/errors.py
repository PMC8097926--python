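"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A cell table, sidecar or clinical file does not match the expected schema."""


class ConfigError(ValueError):
    """An analysis or simulation configuration is invalid."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""
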