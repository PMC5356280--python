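"""Exception hierarchy for the nmrstar package.

Everything raised on malformed input derives from :class:`StarError`, so
callers that stream over many files can catch one type. Lexing and parsing
errors carry the 1-based line number where the problem was detected.
"""

from __future__ import annotations


class StarError(Exception):
    """Base class for all nmrstar errors."""


class StarLexError(StarError):
    """Raised by the tokenizer on lexically malformed input."""

    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"{message} (line {line})")
        self.line = line


class StarParseError(StarError):
    """Raised by the parser on structurally malformed token streams."""

    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class InvalidEntryError(StarError):
    """Raised when an entry fails model validation (e.g. before writing)."""


class UnrepresentableValueError(StarError):
    """Raised for a value the STAR grammar cannot encode.

    A value containing a line that begins with ";" cannot be placed inside a
    semicolon-delimited block (the column-1 semicolon would terminate it) and
    the grammar offers no escape mechanism.
    """


class StarJsonError(StarError):
    """Raised on malformed JSONized NMR-STAR input (schema violations)."""


class SourceResolutionError(StarError):
    """Raised when an input specification cannot be resolved to documents."""


class MissingShiftDataError(StarError):
    """Raised when an entry contains no assigned-chemical-shift loop."""
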