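"""Exception types shared across the package."""


class QuotaSyntenyError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(QuotaSyntenyError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(QuotaSyntenyError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConsistencyError(QuotaSyntenyError, ValueError):
    """Cross-referenced objects disagree (e.g. a constraint names an unknown block)."""


class UnsupportedOperationError(QuotaSyntenyError, NotImplementedError):
    """The requested operation is outside the tool's supported regime."""
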