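"""Exception hierarchy shared across the package."""


class DoxOrigamiError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DoxOrigamiError):
    """A file could not be parsed (malformed rows, duplicate keys, ...)."""


class ValidationError(DoxOrigamiError):
    """A domain object violates one of its invariants."""


class DomainError(DoxOrigamiError):
    """An argument is outside the mathematical domain of an operation."""


class DataError(DoxOrigamiError):
    """Measured data is inconsistent beyond the allowed noise tolerance."""


class SaturationError(DomainError):
    """The observable sits at its saturation limit; the inversion is degenerate.

    Raised by the quantum-yield inversion when the measured quenching equals
    the fully-bound (1:2 complex) limit; callers should treat the bound
    fraction as 1 instead of inverting.
    """


class FitError(DoxOrigamiError):
    """A nonlinear fit failed to converge or produced unusable parameters."""
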