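"""Exception types shared across the package."""


class LncnetError(Exception):
    """Base class for package errors."""


class ParseError(LncnetError, ValueError):
    """A file could not be parsed (malformed row, missing cell, bad header)."""


class ValidationError(LncnetError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateDataError(LncnetError, ValueError):
    """Data are valid but degenerate for the requested statistic
    (zero variance, no events, too few distinct degrees, ...)."""
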