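"""Ordered nested mapping model of an NMR-STAR entry.

One parsed entry is a :class:`StarEntry`: an insertion-ordered mapping whose
reserved first key ``"data"`` holds the data-block identifier and whose
remaining keys are saveframe names (mapping to :class:`Saveframe`), or —
for tags and loops appearing at data-block level, which is legal STAR —
tag keys, ``loop_N`` keys and (when comment capture is on) ``comment_N``
keys. A :class:`Saveframe` is the same kind of ordered mapping one level
down; a :class:`Loop` is a pair of (field-name list, record list), each
record an ordered mapping from field tag to value string.

All values are strings everywhere: the model performs no numeric coercion,
which is what makes the NMR-STAR ↔ model ↔ JSON round trip lossless.
"""

from __future__ import annotations

import re
from typing import Iterator, Mapping, NamedTuple

__all__ = [
    "StarEntry",
    "Saveframe",
    "Loop",
    "structurally_equal",
    "validate",
    "iter_key_paths",
]

_LOOP_KEY = re.compile(r"loop_(\d+)$")
_COMMENT_KEY = re.compile(r"comment_(\d+)$")


class Saveframe(dict):
    """Ordered mapping of tags, loops (``loop_N``) and comments (``comment_N``)."""

    __slots__ = ()


class StarEntry(dict):
    """Top-level ordered mapping representing one NMR-STAR data block.

    Attributes
    ----------
    source:
        Provenance descriptor (path, URL, ``archive::member``, BMRB id).
        Excluded from structural comparison.
    """

    __slots__ = ("source",)

    def __init__(self, *args, source: str = "", **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.source = source

    @property
    def id(self) -> str:
        """The data-block identifier (reserved key ``"data"``)."""
        return self.get("data", "")


class Loop(NamedTuple):
    """A loop table: ordered field names plus row-major records."""

    fields: list
    records: list


def structurally_equal(a, b) -> bool:
    """Order-sensitive deep equality of entries (source descriptors ignored).

    True iff ``a`` and ``b`` have identical key sequences at every nesting
    level and identical value strings.
    """
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    if isinstance(a, Loop) or isinstance(b, Loop):
        if not (isinstance(a, Loop) and isinstance(b, Loop)):
            return False
        if list(a.fields) != list(b.fields) or len(a.records) != len(b.records):
            return False
        return all(structurally_equal(ra, rb) for ra, rb in zip(a.records, b.records))
    if isinstance(a, Mapping) and isinstance(b, Mapping):
        if list(a.keys()) != list(b.keys()):
            return False
        return all(structurally_equal(a[k], b[k]) for k in a)
    return False


def iter_key_paths(entry: Mapping) -> Iterator[str]:
    """Yield the flattened key paths of an entry in document order.

    ``data``, then for each saveframe its name followed by ``name/key`` for
    every key inside it; data-block-level tags/loops/comments appear under
    their own keys. Used to assert insertion-order preservation.
    """
    for key, value in entry.items():
        yield key
        if isinstance(value, Mapping):
            for inner in value:
                yield f"{key}/{inner}"


def _check_numbering(keys, pattern, what, path, out) -> None:
    numbers = [int(m.group(1)) for k in keys if (m := pattern.match(k))]
    if numbers != list(range(len(numbers))):
        out.append(
            f"{path}: {what} keys not consecutively numbered from 0: "
            f"{[f'{what}_{n}' for n in numbers]}"
        )


def _validate_loop(loop: Loop, path: str, out) -> None:
    if not loop.fields:
        out.append(f"{path}: loop has no fields")
        return
    for f in loop.fields:
        if not isinstance(f, str) or not f.startswith("_"):
            out.append(f"{path}: loop field {f!r} does not begin with '_'")
    if len(set(loop.fields)) != len(loop.fields):
        out.append(f"{path}: duplicate loop field names")
    fields = list(loop.fields)
    for i, record in enumerate(loop.records):
        if not isinstance(record, Mapping) or list(record.keys()) != fields:
            out.append(f"{path}/record {i}: record keys do not match loop fields")
            continue
        for v in record.values():
            if not isinstance(v, str):
                out.append(f"{path}/record {i}: non-string value {v!r}")


def _validate_frame_items(mapping: Mapping, path: str, out, allow_frames: bool) -> None:
    _check_numbering(list(mapping), _LOOP_KEY, "loop", path, out)
    _check_numbering(list(mapping), _COMMENT_KEY, "comment", path, out)
    for key, value in mapping.items():
        if key == "data":
            continue
        here = f"{path}/{key}" if path else key
        if isinstance(value, Loop):
            if not _LOOP_KEY.match(key):
                out.append(f"{here}: loop stored under non-loop key")
            _validate_loop(value, here, out)
        elif isinstance(value, Mapping):
            if not allow_frames:
                out.append(f"{here}: nested saveframe is not allowed")
            else:
                _validate_frame_items(value, f"save_{key}", out, allow_frames=False)
        elif isinstance(value, str):
            if not (key.startswith("_") or _COMMENT_KEY.match(key)):
                out.append(f"{here}: scalar under key that is neither a tag nor a comment")
        else:
            out.append(f"{here}: unsupported value type {type(value).__name__}")


def validate(entry: Mapping) -> list[str]:
    """Check the model invariants; return violation descriptions (empty = valid).

    Checked: reserved ``"data"`` key present and first; tag keys begin with
    ``"_"`` and map to strings; ``loop_N``/``comment_N`` keys consecutively
    numbered from 0 per nesting level; every loop record's key sequence
    equals the loop's field list exactly, in order.
    """
    out: list[str] = []
    keys = list(entry)
    if "data" not in entry:
        out.append("entry: reserved key 'data' is missing")
    else:
        if keys[0] != "data":
            out.append("entry: reserved key 'data' must precede all other keys")
        if not isinstance(entry["data"], str):
            out.append("entry: 'data' identifier is not a string")
    _validate_frame_items(entry, "", out, allow_frames=True)
    return out
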