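"""Exception types raised by cashde validation and parsing."""


class CashdeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CashdeError, ValueError):
    """Input violates a structural invariant (duplicates, NaN, bad groups ...)."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending cell."""
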