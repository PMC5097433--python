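"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class ValidationError(ValueError):
    """An input violates a structural precondition (shape, symmetry, range)."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (catalogue vs truth, family vs members) do not."""
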