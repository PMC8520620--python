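"""Exception types raised by ccxover."""


class CcxoverError(Exception):
    """Base class for all ccxover errors."""


class ValidationError(CcxoverError):
    """Malformed input data (missing periods, non-binary values, ...)."""


class DegenerateDataError(CcxoverError):
    """No discordant information in one of the two directions.

    Raised when ``a1 == 0`` or ``a0 == 0`` (or the corresponding person-time
    sums vanish), so the relative case-period exposure probability pi10 and
    hence the weighting method are undefined.
    """


class NoInformativeCasesError(CcxoverError):
    """Every case failed the positivity condition of the permutation likelihood."""
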