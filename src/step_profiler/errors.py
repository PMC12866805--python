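"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object violates its invariants.

    The message always names the offending field.
    """


class ValidationError(ValueError):
    """An input table or matrix violates a data contract."""
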