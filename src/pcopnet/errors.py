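"""Exception hierarchy shared across the package."""


class PcopnetError(Exception):
    """Base class for all package errors."""


class ParseError(PcopnetError):
    """Malformed input file (bad header, non-numeric cell, ...)."""


class ValidationError(PcopnetError):
    """Input violates a structural invariant (duplicate ids, no analysable genes)."""


class InsufficientDataError(PcopnetError):
    """Too few data points for a PCOP fit."""


class DegenerateInputError(PcopnetError):
    """Data cloud carries no geometric information (all points coincide)."""


class ParameterError(PcopnetError):
    """A parameter lies outside its valid range."""


class ThresholdError(PcopnetError):
    """A threshold formula degenerates for the given matrix size."""


class UnknownGeneError(PcopnetError, KeyError):
    """A queried gene id is absent from the data."""


class SpecError(PcopnetError):
    """A synthetic-data specification cannot be satisfied."""
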