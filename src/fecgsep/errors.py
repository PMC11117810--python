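"""Exception hierarchy shared across the package."""


class FecgError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FecgError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(FecgError):
    """The requested fetal energy fraction cannot be attained."""


class DegenerateInputError(FecgError):
    """Input is rank-deficient or otherwise uninformative."""


class NotWhitenedError(FecgError):
    """ICA received data whose sample covariance is not the identity."""


class UndefinedIndexError(FecgError):
    """Performance index is undefined (zero row or column in |G|)."""


class FormatError(FecgError):
    """A file does not match the declared CSV dialect."""
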