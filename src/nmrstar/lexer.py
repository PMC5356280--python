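"""Tokenizer for the NMR-STAR flat-file grammar.

NMR-STAR is the BMRB's dialect of the STAR (Self-defining Text Archival and
Retrieving) format: a ``data_<id>`` block containing named saveframes
(``save_<name>`` ... ``save_``), free tag/value pairs and loops
(``loop_`` ... ``stop_``). :func:`tokenize` performs a single left-to-right
pass over the document and lazily yields classified :class:`Token` objects.

Quoting forms handled:

* bare (whitespace-delimited) words, including the ``.`` / ``?`` null and
  unknown placeholders and ``$framecode`` references, all preserved verbatim;
* single- and double-quoted strings, where the closing quote is recognised
  only when the quote character is immediately followed by whitespace or
  end-of-line — a quote anywhere else is literal content;
* semicolon-delimited multiline blocks opened and closed by a ``;`` in
  column 1. Block content keeps internal newlines and internal semicolons
  verbatim; the closing delimiter line may be immediately followed by the
  next token (e.g. ``;loop_``), which some widely used parsers mishandle.

``#`` starts a comment only at the start of a whitespace-delimited position
and runs to end of line. Keywords are matched case-insensitively. CRLF line
endings are normalised to LF before column-1 detection.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterator

from .exceptions import StarLexError

__all__ = ["Token", "TokenKind", "tokenize"]

log = logging.getLogger(__name__)


class TokenKind(enum.Enum):
    DATA_HEADER = "data_header"
    SAVE_BEGIN = "save_begin"
    SAVE_END = "save_end"
    LOOP_BEGIN = "loop_begin"
    LOOP_END = "loop_end"
    TAG = "tag"
    VALUE = "value"
    COMMENT = "comment"


@dataclass(frozen=True)
class Token:
    """One lexical unit: kind, decoded payload and 1-based start line.

    ``text`` excludes delimiters: for DATA_HEADER/SAVE_BEGIN it is the
    identifier after the keyword prefix, for quoted and multiline VALUEs the
    content between delimiters, for COMMENT the text after ``#``.
    """

    kind: TokenKind
    text: str
    line: int


_WS = " \t\n"


def _classify_word(word: str, line: int) -> Token:
    lowered = word.lower()
    if lowered.startswith("data_") and len(word) > 5:
        return Token(TokenKind.DATA_HEADER, word[5:], line)
    if lowered == "save_":
        return Token(TokenKind.SAVE_END, "", line)
    if lowered.startswith("save_") and len(word) > 5:
        return Token(TokenKind.SAVE_BEGIN, word[5:], line)
    if lowered == "loop_":
        return Token(TokenKind.LOOP_BEGIN, "", line)
    if lowered == "stop_":
        return Token(TokenKind.LOOP_END, "", line)
    if word.startswith("_"):
        return Token(TokenKind.TAG, word, line)
    return Token(TokenKind.VALUE, word, line)


def tokenize(text: str, emit_comments: bool = False) -> Iterator[Token]:
    """Lazily yield :class:`Token` objects for an NMR-STAR document.

    Parameters
    ----------
    text:
        The complete document (may be empty). LF or CRLF line endings.
    emit_comments:
        When true, ``#`` comments are yielded as COMMENT tokens; otherwise
        they are consumed and discarded.

    Raises
    ------
    StarLexError
        On an unterminated quoted string (end of line reached) or an
        unterminated multiline block (end of file reached).
    """
    if "\r" in text:
        text = text.replace("\r\n", "\n")
    n = len(text)
    i = 0
    line = 1
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            i += 1
            continue
        if c == " " or c == "\t":
            i += 1
            continue
        at_col1 = i == 0 or text[i - 1] == "\n"
        start_line = line
        if c == ";" and at_col1:
            # Multiline block: content runs from just after the opening ";"
            # to the newline preceding the next column-1 ";". Exactly one
            # leading newline (the opening delimiter line's) is stripped.
            i += 1
            content_start = i
            close = -1
            while i < n:
                if text[i] == "\n":
                    line += 1
                    if i + 1 < n and text[i + 1] == ";":
                        close = i
                        break
                i += 1
            if close < 0:
                raise StarLexError("unterminated multiline value", start_line)
            value = text[content_start:close]
            if value.startswith("\n"):
                value = value[1:]
            i = close + 2  # past the newline and the closing ";"
            yield Token(TokenKind.VALUE, value, start_line)
        elif c == "'" or c == '"':
            quote = c
            i += 1
            content_start = i
            while True:
                if i >= n or text[i] == "\n":
                    raise StarLexError("unterminated quoted value", start_line)
                if text[i] == quote and (i + 1 >= n or text[i + 1] in _WS):
                    break
                i += 1
            value = text[content_start:i]
            i += 1  # past the closing quote
            yield Token(TokenKind.VALUE, value, start_line)
        elif c == "#":
            i += 1
            content_start = i
            while i < n and text[i] != "\n":
                i += 1
            if emit_comments:
                yield Token(TokenKind.COMMENT, text[content_start:i], start_line)
        else:
            word_start = i
            while i < n and text[i] not in _WS:
                i += 1
            yield _classify_word(text[word_start:i], start_line)
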