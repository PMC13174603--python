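"""Package-wide exception types."""


class DevgeomError(Exception):
    """Base class for all devgeom errors."""


class ValidationError(DevgeomError, ValueError):
    """An input violated a documented precondition or invariant.

    Where a single field is at fault, the message names it.
    """


class DegenerateDataError(DevgeomError, ValueError):
    """Data are degenerate for the requested computation.

    Raised for zero-variance patterns, coincident point configurations,
    zero-area hulls, and similar cases where the statistic is undefined.
    """
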