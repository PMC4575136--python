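"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied data (sequences, matrices, options) is invalid."""


class SizeGuardError(InputError):
    """Raised when a brute-force oracle is asked to handle inputs too large to enumerate."""
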