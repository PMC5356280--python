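"""Lossless bidirectional mapping between entries and JSON, plus bulk conversion.

The JSON schema mirrors the model one-to-one: the entry is an object whose
member order is significant (``"data"`` first, then saveframes as nested
objects); each loop is a two-element array ``[fields, records]`` — the
model's pair of lists — and every scalar is a JSON string. Python's ``json``
module preserves object member order on both ends (dicts are
insertion-ordered), which is the property that makes the mapping lossless.

:func:`convert` performs one-to-one (single file) and many-to-many
(directory or zip/tar archive) conversion between the NMR-STAR and JSON
representations, mirroring member structure and streaming one document at a
time.
"""

from __future__ import annotations

import io
import json
import logging
import tarfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import StarJsonError
from .model import Loop, Saveframe, StarEntry, validate
from .parser import parse_text
from .writer import star_text
from . import sources as _sources

__all__ = ["to_json_text", "from_json_text", "convert", "ConversionReport"]

log = logging.getLogger(__name__)


def _jsonable(node):
    if isinstance(node, Loop):
        return [list(node.fields), [dict(r) for r in node.records]]
    if isinstance(node, Mapping):
        return {k: _jsonable(v) for k, v in node.items()}
    return node


def to_json_text(entry: StarEntry, *, indent: int | None = None) -> str:
    """Serialize a valid entry as JSON text (UTF-8 friendly, no BOM).

    Compact by default; pass ``indent=4`` for pretty-printed output.
    """
    violations = validate(entry)
    if violations:
        raise StarJsonError(f"cannot JSONize invalid entry: {violations[0]}")
    return json.dumps(_jsonable(entry), ensure_ascii=False, indent=indent)


def _loop_from_json(node, path: str) -> Loop:
    if len(node) != 2:
        raise StarJsonError(f"{path}: loop array must have exactly 2 elements")
    fields, records = node
    if not isinstance(fields, list) or not all(isinstance(f, str) for f in fields):
        raise StarJsonError(f"{path}: loop field list must be an array of strings")
    out_records = []
    for i, record in enumerate(records if isinstance(records, list) else ()):
        if not isinstance(record, dict) or list(record.keys()) != fields:
            raise StarJsonError(f"{path}/record {i}: record keys do not match field list")
        for v in record.values():
            if not isinstance(v, str):
                raise StarJsonError(f"{path}/record {i}: non-string value {v!r}")
        out_records.append(dict(record))
    if not isinstance(records, list):
        raise StarJsonError(f"{path}: loop records must be an array")
    return Loop(list(fields), out_records)


def _frame_from_json(node: dict, path: str) -> Saveframe:
    frame = Saveframe()
    for key, value in node.items():
        here = f"{path}/{key}"
        if isinstance(value, str):
            frame[key] = value
        elif isinstance(value, list):
            frame[key] = _loop_from_json(value, here)
        else:
            raise StarJsonError(f"{here}: unsupported JSON node type")
    return frame


def from_json_text(text: str) -> StarEntry:
    """Reconstruct a :class:`StarEntry` from JSONized NMR-STAR text.

    Key order follows JSON document order. Raises :class:`StarJsonError` on
    malformed JSON or schema violations (naming the offending path).
    """
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StarJsonError(f"malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise StarJsonError("top-level JSON node must be an object")
    entry = StarEntry()
    for key, value in obj.items():
        if isinstance(value, str):
            entry[key] = value
        elif isinstance(value, list):
            entry[key] = _loop_from_json(value, key)
        elif isinstance(value, dict):
            entry[key] = _frame_from_json(value, key)
        else:
            raise StarJsonError(f"{key}: unsupported JSON node type")
    return entry


@dataclass
class ConversionReport:
    """Outcome of a bulk conversion: members attempted, written, failed."""

    source: str
    target: str
    attempted: int = 0
    succeeded: int = 0
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.attempted == self.succeeded


_EXT_FOR = {"nmrstar": ".str", "json": ".json"}


def _converted_name(name: str, to_format: str) -> str:
    stem, dot, ext = name.rpartition(".")
    if dot and ext.lower() in ("str", "json", "txt", "star", "nmrstar"):
        return stem + _EXT_FOR[to_format]
    return name + _EXT_FOR[to_format]


def _convert_document(text: str, from_format: str, to_format: str,
                      indent: int | None, strict: bool) -> str:
    entry = (
        from_json_text(text)
        if from_format == "json"
        else parse_text(text, strict=strict)
    )
    if to_format == "json":
        return to_json_text(entry, indent=indent)
    return star_text(entry)


class _DirSink:
    def __init__(self, root: Path) -> None:
        self.root = root
        root.mkdir(parents=True, exist_ok=True)

    def add(self, name: str, text: str) -> None:
        path = self.root / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text, encoding="utf-8")

    def close(self) -> None:
        pass


class _ZipSink:
    def __init__(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        self._zip = zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED)

    def add(self, name: str, text: str) -> None:
        self._zip.writestr(name, text)

    def close(self) -> None:
        self._zip.close()


class _TarSink:
    def __init__(self, path: Path, mode: str) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        self._tar = tarfile.open(path, mode)

    def add(self, name: str, text: str) -> None:
        data = text.encode("utf-8")
        info = tarfile.TarInfo(name)
        info.size = len(data)
        self._tar.addfile(info, io.BytesIO(data))

    def close(self) -> None:
        self._tar.close()


def _make_sink(target: Path, source_kind: str):
    name = target.name.lower()
    if name.endswith(".zip"):
        return _ZipSink(target)
    if name.endswith((".tar.gz", ".tgz")):
        return _TarSink(target, "w:gz")
    if name.endswith((".tar.bz2", ".tbz2")):
        return _TarSink(target, "w:bz2")
    if name.endswith(".tar"):
        return _TarSink(target, "w")
    if source_kind == _sources.SourceKind.LOCAL_DIR.name or "." not in name:
        return _DirSink(target)
    # fall back to mirroring the source archive kind under the given name
    return _DirSink(target)


def convert(
    source,
    target,
    *,
    from_format: str,
    to_format: str,
    indent: int | None = None,
    strict: bool = True,
    glob: str | None = None,
) -> ConversionReport:
    """Convert between NMR-STAR and JSONized NMR-STAR representations.

    ``source`` may be a path/URL/BMRB-id string or a resolved
    :class:`~nmrstar.sources.SourceSpec`. A single-file source is converted
    one-to-one into the file named by ``target``; a directory or archive
    source is converted many-to-many, mirroring member structure into a
    target directory or archive (kind inferred from the target extension).
    Members that fail to parse are reported in the returned
    :class:`ConversionReport` and skipped.
    """
    if from_format == to_format:
        raise ValueError("from_format and to_format must differ")
    for fmt in (from_format, to_format):
        if fmt not in _EXT_FOR:
            raise ValueError(f"unknown format {fmt!r}")

    spec = _sources.make_spec(source) if isinstance(source, str) else source
    target = Path(target)
    report = ConversionReport(source=spec.raw, target=str(target))
    pairs: Iterable[tuple[str, str]] = _sources.resolve(spec, glob=glob)

    single = spec.kind in (
        _sources.SourceKind.LOCAL_FILE,
        _sources.SourceKind.URL_FILE,
        _sources.SourceKind.BMRB_ID,
    )
    if single:
        for name, text in pairs:
            report.attempted += 1
            try:
                converted = _convert_document(text, from_format, to_format, indent, strict)
            except Exception as exc:  # reported, not raised: bulk contract
                log.error("failed to convert %s: %s", name, exc)
                report.failures.append((name, str(exc)))
                continue
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(converted, encoding="utf-8")
            report.succeeded += 1
        return report

    sink = _make_sink(target, spec.kind.name)
    try:
        for name, text in pairs:
            report.attempted += 1
            try:
                converted = _convert_document(text, from_format, to_format, indent, strict)
            except Exception as exc:
                log.error("failed to convert member %s: %s", name, exc)
                report.failures.append((name, str(exc)))
                continue
            finally:
                text = None  # release before fetching the next member
            sink.add(_converted_name(name, to_format), converted)
            converted = None
            report.succeeded += 1
    finally:
        sink.close()
    return report
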