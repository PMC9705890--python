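class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class InputError(OSError):
    """A referenced file or directory is missing or unreadable."""
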