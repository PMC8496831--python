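"""Exception types shared across the package."""


class DetiError(Exception):
    """Base class for all package errors."""


class ArgumentError(DetiError, ValueError):
    """An argument violates a precondition (bad shape, range, or size)."""


class DegenerateInputError(DetiError, ValueError):
    """Input is structurally valid but statistically degenerate
    (constant image, zero-norm vector, all trials rejected, ...)."""
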