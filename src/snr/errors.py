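"""Exception types shared across the package.

Every malformed input raises a typed error; silent coercion is never used.
"""


class SnrError(Exception):
    """Base class for all package errors."""


class ValidationError(SnrError, ValueError):
    """An input violated a documented invariant or precondition."""


class ParseError(SnrError, ValueError):
    """A file could not be parsed; the message carries location info."""
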