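"""Exception hierarchy for pam3p.

All package-specific failures derive from :class:`PAMError` so callers can
catch one base class; most are also ``ValueError`` subclasses because they
signal invalid arguments or geometry.
"""


class PAMError(Exception):
    """Base class for all pam3p errors."""


class InvalidArgumentError(PAMError, ValueError):
    """An argument violates a precondition (sign, range, emptiness)."""


class GeometryError(PAMError, ValueError):
    """Grids, shapes or positions are mutually inconsistent."""


class ResolutionError(InvalidArgumentError):
    """A sampling pitch is too coarse to resolve the requested structure."""


class PlacementError(PAMError, RuntimeError):
    """Random object placement failed after bounded retries."""


class WindowError(PAMError, ValueError):
    """A time window falls (partly) outside the available trace."""


class AlignmentError(PAMError, ValueError):
    """Traces to be combined differ in length or trigger alignment."""


class CompletenessError(PAMError, ValueError):
    """A trace set is missing data for one or more pixels."""


class DomainError(InvalidArgumentError):
    """Data outside the mathematical domain of a fit (e.g. log of <= 0)."""


class DegenerateBaselineError(PAMError, ZeroDivisionError):
    """A dF/F baseline is zero, so the ratio is undefined."""
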