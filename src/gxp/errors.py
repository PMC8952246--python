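"""Exception hierarchy shared across the package."""


class GxpError(Exception):
    """Base class for all errors raised by this package."""


class TableFormatError(GxpError):
    """An input table violates the expected structure or grammar."""


class ValidationError(GxpError):
    """An argument or data structure fails a documented precondition."""
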