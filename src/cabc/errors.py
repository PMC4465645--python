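"""Exception hierarchy for computed ABC analysis."""


class AbcError(ValueError):
    """Base class for all input and parameter errors raised by this package."""


class DataValidationError(AbcError):
    """Input values violate the data contract (negative, non-finite, too few)."""


class DegenerateDataError(AbcError):
    """Data admits no ABC curve (e.g. all values zero: degenerate total yield)."""


class ParameterError(AbcError):
    """A distribution or configuration parameter is outside its domain."""
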