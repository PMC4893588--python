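"""Exception hierarchy for greycast."""


class GreycastError(Exception):
    """Base class for all greycast errors."""


class InvalidInputError(GreycastError, ValueError):
    """Raised when input data violate a precondition (non-positive glucose,
    length mismatch, too-short fitting window, ...)."""


class InvalidConfigError(GreycastError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class UndefinedRatioError(GreycastError, ZeroDivisionError):
    """Raised when the posterior variance ratio C = S2/S1 is undefined
    because the original series is constant (S1 = 0)."""
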