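"""Exception hierarchy shared by all smx modules."""


class SmxError(ValueError):
    """Base class for all smx-specific errors."""


class ValidationError(SmxError):
    """Input violates a documented precondition (range, uniqueness, shape)."""


class FormatError(SmxError):
    """A file does not conform to the expected CSV/JSON layout."""


class DegenerateInputError(SmxError):
    """Input is formally valid but carries no usable signal (zero variance,
    coincident points, constant series)."""


class InsufficientDataError(SmxError):
    """Not enough samples/strides/bouts to run the requested computation."""
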