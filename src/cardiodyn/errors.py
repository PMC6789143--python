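"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class InvalidSpecError(ValueError):
    """Raised when a simulation specification is internally inconsistent."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal
    (e.g. all embedded points identical)."""
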