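"""Exception hierarchy.

Everything raised by this package derives from :class:`OvReserveError`,
which itself derives from :class:`ValueError` so that callers who do not
care about the distinction can catch the builtin.
"""


class OvReserveError(ValueError):
    """Base class for all errors raised by ovreserve."""


class CalibrationError(OvReserveError):
    """Anchor values cannot define a valid two-phase decay model."""


class DomainError(OvReserveError):
    """Argument outside the physical/mathematical domain of an operation."""


class ParameterError(OvReserveError):
    """Invalid numerical parameter (e.g. non-positive integration step)."""


class ConfigurationError(OvReserveError):
    """Invalid grid/config specification, or one that yields no data."""


class FittingError(OvReserveError):
    """Regression cannot be fitted (too few points, degenerate design)."""


class InputFormatError(OvReserveError):
    """Batch input file does not match the expected schema."""
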