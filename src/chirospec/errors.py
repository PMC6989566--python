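"""Exception hierarchy shared across the package."""


class ChirospecError(Exception):
    """Base class for all package errors."""


class FormatError(ChirospecError):
    """A file could not be parsed (the message names the offending line)."""


class ValidationError(ChirospecError):
    """An input value violates a precondition (nonpositive concentration, ...)."""


class UnitError(ChirospecError):
    """Spectral arithmetic or conversion attempted with an incompatible unit tag."""


class AlignmentError(ChirospecError):
    """Spectral arithmetic attempted across mismatched wavelength grids."""


class RangeError(ChirospecError):
    """A requested wavelength, window or grid lies outside the available support."""
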