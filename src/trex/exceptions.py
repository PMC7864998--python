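"""Error types shared across the package."""


class TrexError(Exception):
    """Base class for all package errors."""


class ValidationError(TrexError, ValueError):
    """Raised when input data violates a documented contract."""


class FormatError(TrexError, ValueError):
    """Raised when a file cannot be parsed as the expected format."""
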