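"""Exception hierarchy.

``VoxsiteError`` marks user-facing errors (bad input, bad arguments); anything
else escaping the library is an internal bug.
"""


class VoxsiteError(Exception):
    """Base class for all user-facing errors raised by voxsite."""


class ParseError(VoxsiteError):
    """Malformed structure file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
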