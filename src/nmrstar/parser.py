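"""Recursive-descent construction of a :class:`~nmrstar.model.StarEntry`.

The parser pulls tokens lazily from the tokenizer through a small cursor, so
a document is never materialised as a token list. Construction mirrors the
three grammar levels: the data block dispatches on token kind, saveframes
alternate TAG/VALUE pairs and delegate loops, and loops collect their field
tags followed by row-major values.

Two policies are supported:

* strict (default): duplicate tags, stray values, loops not terminated by
  ``stop_`` and ragged loop tables are format errors;
* lenient: those conditions are repaired where a lossless repair exists
  (keep first tag occurrence, accept ``save_`` as an implicit loop
  terminator, truncate a ragged final record) and logged as warnings.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

from .exceptions import StarParseError
from .lexer import Token, TokenKind, tokenize
from .model import Loop, Saveframe, StarEntry

__all__ = ["parse_text", "build_saveframe", "build_loop", "TokenCursor"]

log = logging.getLogger(__name__)


class TokenCursor:
    """Pull-based cursor over a token stream with one-token pushback."""

    def __init__(self, tokens: Iterable[Token]) -> None:
        self._it: Iterator[Token] = iter(tokens)
        self._pending: list[Token] = []

    def next(self) -> Token | None:
        if self._pending:
            return self._pending.pop()
        return next(self._it, None)

    def push(self, token: Token) -> None:
        self._pending.append(token)


def _store_tag(mapping, tag: Token, value: Token, strict: bool, where: str) -> None:
    if tag.text in mapping:
        if strict:
            raise StarParseError(f"duplicate tag {tag.text} in {where}", tag.line)
        log.warning("duplicate tag %s in %s; keeping first occurrence", tag.text, where)
        return
    mapping[tag.text] = value.text


def _read_tag_value(cursor: TokenCursor, tag: Token, comments: list[Token]) -> Token:
    """Consume tokens after a TAG until its VALUE; buffer any comments."""
    while True:
        token = cursor.next()
        if token is None:
            raise StarParseError(f"tag {tag.text} has no value (end of file)", tag.line)
        if token.kind is TokenKind.COMMENT:
            comments.append(token)
            continue
        if token.kind is not TokenKind.VALUE:
            raise StarParseError(f"tag {tag.text} has no value", tag.line)
        return token


def build_loop(cursor: TokenCursor, *, strict: bool = True, where: str = "loop") -> Loop:
    """Build a :class:`Loop` from a cursor positioned just after LOOP_BEGIN.

    Leading TAG tokens become the field list; VALUE tokens are then grouped
    row-major, ``len(fields)`` per record, until LOOP_END. In lenient mode a
    loop terminated by ``save_`` instead of ``stop_`` is accepted (the
    SAVE_END token is pushed back) and a ragged final record is truncated.
    """
    fields: list[str] = []
    first = True
    while True:
        token = cursor.next()
        if token is None:
            raise StarParseError(f"end of file inside {where}")
        if token.kind is TokenKind.COMMENT:
            continue
        if token.kind is TokenKind.TAG:
            if token.text in fields:
                raise StarParseError(
                    f"duplicate loop field {token.text} in {where}", token.line
                )
            fields.append(token.text)
            first = False
            continue
        if first:
            raise StarParseError(f"{where} declares no fields", token.line)
        cursor.push(token)
        break

    values: list[str] = []
    end_line = None
    while True:
        token = cursor.next()
        if token is None:
            raise StarParseError(f"end of file inside {where} (missing stop_)")
        if token.kind is TokenKind.COMMENT:
            log.debug("discarding comment inside %s (line %d)", where, token.line)
            continue
        if token.kind is TokenKind.VALUE:
            values.append(token.text)
            continue
        if token.kind is TokenKind.LOOP_END:
            end_line = token.line
            break
        if token.kind is TokenKind.SAVE_END and not strict:
            log.warning("%s terminated by save_ instead of stop_ (line %d)", where, token.line)
            cursor.push(token)
            end_line = token.line
            break
        raise StarParseError(
            f"unexpected {token.kind.value} token among {where} values", token.line
        )

    if not values:
        log.warning("%s has fields but no records", where)
    remainder = len(values) % len(fields)
    if remainder:
        if strict:
            raise StarParseError(
                f"{where}: {len(values)} values not divisible by {len(fields)} fields",
                end_line,
            )
        log.warning("%s: truncating ragged final record (%d stray values)", where, remainder)
        values = values[: len(values) - remainder]

    records = [
        dict(zip(fields, values[i : i + len(fields)]))
        for i in range(0, len(values), len(fields))
    ]
    return Loop(fields, records)


def build_saveframe(
    cursor: TokenCursor, *, strict: bool = True, capture_comments: bool = False,
    name: str = "saveframe",
) -> Saveframe:
    """Build a :class:`Saveframe` from a cursor positioned just after SAVE_BEGIN.

    Consumes tokens through the matching SAVE_END, alternating TAG/VALUE
    pairs and delegating LOOP_BEGIN to :func:`build_loop` (stored under the
    next ``loop_N`` key).
    """
    frame = Saveframe()
    where = f"save_{name}"
    n_loops = 0
    n_comments = 0
    while True:
        token = cursor.next()
        if token is None:
            raise StarParseError(f"end of file inside {where} (missing save_)")
        kind = token.kind
        if kind is TokenKind.SAVE_END:
            return frame
        if kind is TokenKind.TAG:
            comments: list[Token] = []
            value = _read_tag_value(cursor, token, comments)
            _store_tag(frame, token, value, strict, where)
            for comment in comments:
                if capture_comments:
                    frame[f"comment_{n_comments}"] = comment.text
                    n_comments += 1
        elif kind is TokenKind.LOOP_BEGIN:
            frame[f"loop_{n_loops}"] = build_loop(
                cursor, strict=strict, where=f"{where}/loop_{n_loops}"
            )
            n_loops += 1
        elif kind is TokenKind.COMMENT:
            if capture_comments:
                frame[f"comment_{n_comments}"] = token.text
                n_comments += 1
        elif kind is TokenKind.VALUE:
            if strict:
                raise StarParseError(f"value without a tag in {where}", token.line)
            log.warning("skipping stray value in %s (line %d)", where, token.line)
        else:
            raise StarParseError(f"unexpected {kind.value} token in {where}", token.line)


def parse_text(
    text: str, *, strict: bool = True, capture_comments: bool = False
) -> StarEntry:
    """Parse an NMR-STAR document into a :class:`StarEntry`.

    Parameters
    ----------
    text:
        Complete document text.
    strict:
        Error policy; see the module docstring.
    capture_comments:
        When true, comments become ``comment_N`` keys at the nesting level
        where they occurred (comments inside loops are discarded).

    Raises
    ------
    StarParseError
        If no ``data_`` header precedes the content, or on any structural
        error under the strict policy.
    StarLexError
        Propagated from the tokenizer, with line numbers.
    """
    cursor = TokenCursor(tokenize(text, emit_comments=capture_comments))
    entry = StarEntry()

    leading_comments: list[Token] = []
    while True:
        token = cursor.next()
        if token is None or token.kind is not TokenKind.COMMENT:
            break
        leading_comments.append(token)
    if token is None or token.kind is not TokenKind.DATA_HEADER:
        raise StarParseError(
            "document does not begin with a data_ header",
            token.line if token else None,
        )
    entry["data"] = token.text

    n_loops = 0
    n_comments = 0
    if capture_comments:
        for comment in leading_comments:
            entry[f"comment_{n_comments}"] = comment.text
            n_comments += 1

    while True:
        token = cursor.next()
        if token is None:
            return entry
        kind = token.kind
        if kind is TokenKind.SAVE_BEGIN:
            frame = build_saveframe(
                cursor, strict=strict, capture_comments=capture_comments,
                name=token.text,
            )
            if token.text in entry:
                if strict:
                    raise StarParseError(
                        f"duplicate saveframe name {token.text}", token.line
                    )
                log.warning("duplicate saveframe %s; keeping first", token.text)
            else:
                entry[token.text] = frame
        elif kind is TokenKind.TAG:
            comments: list[Token] = []
            value = _read_tag_value(cursor, token, comments)
            _store_tag(entry, token, value, strict, "data block")
            for comment in comments:
                if capture_comments:
                    entry[f"comment_{n_comments}"] = comment.text
                    n_comments += 1
        elif kind is TokenKind.LOOP_BEGIN:
            entry[f"loop_{n_loops}"] = build_loop(
                cursor, strict=strict, where=f"loop_{n_loops}"
            )
            n_loops += 1
        elif kind is TokenKind.COMMENT:
            if capture_comments:
                entry[f"comment_{n_comments}"] = token.text
                n_comments += 1
        elif kind is TokenKind.DATA_HEADER:
            log.warning(
                "multiple data_ blocks in one document; keeping the first "
                "(second begins at line %d)", token.line,
            )
            return entry
        elif kind is TokenKind.VALUE:
            if strict:
                raise StarParseError("value without a tag at data-block level", token.line)
            log.warning("skipping stray value at data-block level (line %d)", token.line)
        else:
            raise StarParseError(
                f"unexpected {kind.value} token at data-block level", token.line
            )
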