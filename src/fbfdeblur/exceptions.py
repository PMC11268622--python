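"""Package-specific exception types."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain (e.g. negative PSF length)."""


class DivergenceError(RuntimeError):
    """The iteration objective grew far above its running minimum.

    Raised by the solver when the objective exceeds 10x its best observed
    value, which for a correctly configured step size cannot happen; it
    almost always indicates a step size above 1/L.
    """
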