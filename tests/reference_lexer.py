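"""Brute-force reference automaton for the NMR-STAR tokenizer.

Independent re-implementation of the lexical grammar as an explicit
per-character state machine (no code shared with ``nmrstar.lexer``), used as
the oracle in differential tests: on any lexable document the production
tokenizer and this automaton must emit identical token streams.
"""

from __future__ import annotations

import enum
import re


class RefLexError(Exception):
    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"{message} at line {line}")
        self.line = line


class _State(enum.Enum):
    GAP = 0
    WORD = 1
    QUOTE = 2
    MULTI = 3
    COMMENT = 4


_DATA_RE = re.compile(r"data_(.+)$", re.IGNORECASE | re.DOTALL)
_SAVE_RE = re.compile(r"save_(.*)$", re.IGNORECASE | re.DOTALL)


def _word_token(word: str, line: int) -> tuple:
    match = _DATA_RE.match(word)
    if match:
        return ("data_header", match.group(1), line)
    match = _SAVE_RE.match(word)
    if match:
        if match.group(1) == "":
            return ("save_end", "", line)
        return ("save_begin", match.group(1), line)
    if word.lower() == "loop_":
        return ("loop_begin", "", line)
    if word.lower() == "stop_":
        return ("loop_end", "", line)
    if word[0] == "_":
        return ("tag", word, line)
    return ("value", word, line)


def reference_tokenize(text: str, emit_comments: bool = False) -> list:
    """Return [(kind name, payload, line), ...] for a document."""
    text = text.replace("\r\n", "\n")
    tokens: list = []
    state = _State.GAP
    buffer: list = []
    token_line = 0
    quote_char = ""
    column = 0  # column of the character being processed, 1-based
    line = 1

    chars = list(text)
    n = len(chars)
    index = 0
    while index <= n:
        at_end = index == n
        char = "" if at_end else chars[index]
        lookahead = chars[index + 1] if index + 1 < n else ""
        column = 1 if index == 0 or (index > 0 and chars[index - 1] == "\n") else column + 1

        if state is _State.GAP:
            if at_end:
                break
            if char in " \t\n":
                pass
            elif char == ";" and column == 1:
                state = _State.MULTI
                buffer = []
                token_line = line
            elif char in "'\"":
                state = _State.QUOTE
                quote_char = char
                buffer = []
                token_line = line
            elif char == "#":
                state = _State.COMMENT
                buffer = []
                token_line = line
            else:
                state = _State.WORD
                buffer = [char]
                token_line = line
        elif state is _State.WORD:
            if at_end or char in " \t\n":
                tokens.append(_word_token("".join(buffer), token_line))
                state = _State.GAP
            else:
                buffer.append(char)
        elif state is _State.QUOTE:
            if at_end or char == "\n":
                raise RefLexError("quoted value never closed", token_line)
            if char == quote_char and (lookahead in " \t\n" or index + 1 == n):
                tokens.append(("value", "".join(buffer), token_line))
                state = _State.GAP
            else:
                buffer.append(char)
        elif state is _State.MULTI:
            if at_end:
                raise RefLexError("multiline value never closed", token_line)
            if char == ";" and column == 1:
                value = "".join(buffer)
                if value.endswith("\n"):
                    value = value[:-1]
                if value.startswith("\n"):
                    value = value[1:]
                tokens.append(("value", value, token_line))
                state = _State.GAP
            else:
                buffer.append(char)
        elif state is _State.COMMENT:
            if at_end or char == "\n":
                if emit_comments:
                    tokens.append(("comment", "".join(buffer), token_line))
                state = _State.GAP
            else:
                buffer.append(char)

        if char == "\n":
            line += 1
        index += 1

    if state is _State.MULTI:
        raise RefLexError("multiline value never closed", token_line)
    if state is _State.QUOTE:
        raise RefLexError("quoted value never closed", token_line)
    return tokens


def as_triples(tokens) -> list:
    """Production Token objects -> comparable (kind name, text, line) triples."""
    return [(t.kind.value, t.text, t.line) for t in tokens]
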