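"""Exception hierarchy shared across the package."""


class PrsAlphaError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PrsAlphaError, ValueError):
    """An argument is outside its mathematically valid range."""


class FormatError(PrsAlphaError, ValueError):
    """An input file or table violates the expected layout."""


class NumericalError(PrsAlphaError, RuntimeError):
    """A numerical routine produced a non-finite or impossible value."""


class EstimationError(PrsAlphaError, RuntimeError):
    """A model fit failed to converge or the design is degenerate."""


class GenerationError(PrsAlphaError, RuntimeError):
    """The simulator could not produce the requested sample."""
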