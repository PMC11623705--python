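"""Exception types shared across the package."""


class PatliteError(Exception):
    """Base class for package-specific errors."""


class FormatError(PatliteError, ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(PatliteError, ValueError):
    """Data violate a domain invariant (e.g. negative raw intensity)."""


class NumericalError(PatliteError, FloatingPointError):
    """Training or inference produced non-finite values."""
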