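"""Serialization of a :class:`~nmrstar.model.StarEntry` back to NMR-STAR text.

The writer walks the entry in insertion order, so the output recalls the
sequential organisation of the original document. Byte-identical
reproduction of the input whitespace is not the contract — structural
equality after a re-parse is (see :func:`nmrstar.model.structurally_equal`).

Layout: one tag/value pair per line; loop field names one per line,
indented; one record per line with single-space separation; multiline
values as column-1 semicolon blocks. Output is LF-terminated UTF-8 and
always ends with a newline.
"""

from __future__ import annotations

from typing import Mapping, TextIO

from .exceptions import InvalidEntryError, UnrepresentableValueError
from .model import Loop, StarEntry, validate

__all__ = ["write_star", "star_text", "format_value"]

_BARE_UNSAFE_LEAD = "_#$;"
_KEYWORD_PREFIXES = ("data_", "save_")
_KEYWORDS = ("loop_", "stop_", "save_")


def _is_keywordish(value: str) -> bool:
    lowered = value.lower()
    return lowered in _KEYWORDS or lowered.startswith(_KEYWORD_PREFIXES)


def format_value(value: str) -> str:
    """Return the minimal safe NMR-STAR encoding of a value string.

    Precedence: bare word, then single-quoted, then double-quoted, then a
    semicolon-delimited multiline block (returned with its surrounding
    newlines, i.e. ``"\\n;\\n...\\n;\\n"``). Placeholders ``.`` and ``?``
    stay bare; keyword-looking values and values with a leading ``_``,
    ``#``, ``$`` or ``;`` are always quoted so they cannot re-lex as
    structure.

    Raises
    ------
    UnrepresentableValueError
        If the value needs block form but contains a line beginning with
        ``;`` — the STAR grammar cannot encode such a string.
    """
    if value == "":
        return "''"
    has_ws = any(c in " \t\n" for c in value)
    has_single = "'" in value
    has_double = '"' in value
    if (
        not has_ws
        and not has_single
        and not has_double
        and value[0] not in _BARE_UNSAFE_LEAD
        and not _is_keywordish(value)
    ):
        return value
    if "\n" not in value:
        if not has_single:
            return f"'{value}'"
        if not has_double:
            return f'"{value}"'
    if any(line.startswith(";") for line in value.split("\n")):
        raise UnrepresentableValueError(
            "value contains a line beginning with ';' and cannot be written "
            "as a semicolon-delimited block"
        )
    return f"\n;\n{value}\n;\n"


def _write_tag(sink: TextIO, tag: str, value: str) -> None:
    fragment = format_value(value)
    if fragment.startswith("\n;"):
        sink.write(f"{tag}{fragment}")
    else:
        sink.write(f"{tag} {fragment}\n")


def _write_loop(sink: TextIO, loop: Loop) -> None:
    sink.write("loop_\n")
    for field in loop.fields:
        sink.write(f"    {field}\n")
    for record in loop.records:
        parts: list[str] = []
        at_line_start = True
        for value in record.values():
            fragment = format_value(value)
            if fragment.startswith("\n;"):
                if parts:
                    sink.write(" ".join(parts))
                    sink.write(fragment)
                    parts = []
                else:
                    sink.write(fragment if not at_line_start else fragment[1:])
                at_line_start = True
            else:
                parts.append(fragment)
                at_line_start = False
        if parts:
            sink.write(" ".join(parts) + "\n")
    sink.write("stop_\n")


def _write_frame_body(sink: TextIO, frame: Mapping) -> None:
    for key, value in frame.items():
        if isinstance(value, Loop):
            _write_loop(sink, value)
        elif key.startswith("_"):
            _write_tag(sink, key, value)
        else:  # captured comment
            sink.write(f"#{value}\n")


def write_star(entry: StarEntry, sink: TextIO) -> None:
    """Serialize ``entry`` as NMR-STAR text into ``sink``.

    The entry must be valid; the first validation violation is raised as
    :class:`InvalidEntryError` otherwise.
    """
    violations = validate(entry)
    if violations:
        raise InvalidEntryError(violations[0])
    sink.write(f"data_{entry['data']}\n")
    for key, value in entry.items():
        if key == "data":
            continue
        if isinstance(value, Loop):
            _write_loop(sink, value)
        elif isinstance(value, Mapping):
            sink.write(f"\nsave_{key}\n")
            _write_frame_body(sink, value)
            sink.write("save_\n")
        elif key.startswith("_"):
            _write_tag(sink, key, value)
        else:
            sink.write(f"#{value}\n")


def star_text(entry: StarEntry) -> str:
    """Return the NMR-STAR serialization of ``entry`` as a string."""
    import io

    buffer = io.StringIO()
    write_star(entry, buffer)
    return buffer.getvalue()
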