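"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter set or config file violates an invariant.

    The message always names the offending key/field and the constraint.
    """


class UsageError(ValueError):
    """An operation was called with inconsistent arguments (e.g. length
    mismatch, empty analysis window)."""
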