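"""Deterministic synthetic NMR-STAR (and JSONized) fixtures with manifests.

Real BMRB entries are large and live behind the network; the generator in
this module emits small NMR-STAR documents with the same structural
repertoire — saveframes, tag/value pairs, loops, comments, every quoting
form — together with a ground-truth manifest of exact counts and key order,
so that the lexer, parser, writer and converters can be validated without
any external data.

Edge flags force the documented hard cases into a document at least once:

* ``EMBEDDED_SEMICOLON`` — a multiline value containing a semicolon that is
  not in column 1 (content, not a delimiter);
* ``MULTILINE_NO_TRAILING_NEWLINE`` — a multiline block whose closing
  column-1 ``;`` is the last character of the file (no trailing newline);
* ``MULTILINE_THEN_LOOP`` — a multiline block whose closing ``;`` is
  immediately followed by ``loop_`` on the same line;
* ``QUOTES_IN_VALUES`` — values containing single/double quotes;
* ``EMPTY_LOOP`` — a loop with fields but zero records;
* ``COMMENTS`` — ``#`` comments at entry and saveframe level;
* ``V21_SHIFTS`` / ``V31_SHIFTS`` — assigned-chemical-shift saveframes in
  the 2.1 and 3.1 tag schemas, built from one shared residue/atom
  composition (drawn from a sub-generator keyed only on the seed) so a
  2.1-only and a 3.1-only fixture with the same seed encode identical
  shifts.

The same spec and seed always produce byte-identical output and manifest.
The value pools deliberately include whitespace, ``#``, ``$``, quotes,
``.``/``?`` placeholders and keyword lookalikes so the writer's quoting
policy is exercised by round trips. The text renderer here is independent
of :mod:`nmrstar.writer` (it chooses its own, randomised encodings), which
is what makes round-trip tests meaningful.
"""

from __future__ import annotations

import io
import json
import random
import tarfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .model import Loop, Saveframe, StarEntry

__all__ = [
    "FixtureSpec",
    "EDGE_FLAGS",
    "generate_entry",
    "expected_entry",
    "iter_corpus",
    "generate_corpus",
    "random_document",
]

EDGE_FLAGS = (
    "EMBEDDED_SEMICOLON",
    "MULTILINE_NO_TRAILING_NEWLINE",
    "MULTILINE_THEN_LOOP",
    "QUOTES_IN_VALUES",
    "EMPTY_LOOP",
    "COMMENTS",
    "V21_SHIFTS",
    "V31_SHIFTS",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_saveframes: int = 3
    loops_per_saveframe: tuple = (0, 2)
    fields_per_loop: tuple = (1, 4)
    records_per_loop: tuple = (0, 5)
    edge_flags: frozenset = frozenset()


_FRAME_WORDS = ["entry_information", "sample_conditions", "spectrometer",
                "citation", "natural_source", "experiment_list", "assembly"]
_TAG_WORDS = ["Details", "Name", "Type", "Temperature", "Field_strength",
              "Mol_common_name", "PH", "Date", "State"]
_FIELD_WORDS = ["ID", "Label", "Code", "Value", "Units", "Count"]

_SIMPLE_VALUES = ["12.5", "-3.2", "0.0071", "298", "600", "yes", "no",
                  "protein", "solution", "pH6.5", "T4-lysozyme", ".", "?",
                  "$sample_one", "$citation_full", "a#b", "C13"]
_SPACED_VALUES = ["assigned chemical shifts", "solution NMR", "wild type",
                  "Helix near C-term", "two  spaces  kept"]
_QUOTEY_VALUES = ["it's fine", 'called "wild type"', "O5' atom", "5'-GMP",
                  "mix 'single' and more", 'she said "stop"']
_TRICKY_VALUES = ["loop_", "stop_", "save_x", "data_7", "#not-a-comment",
                  "_looks_like_tag", ";semistart", ""]
_MULTILINE_VALUES = [
    "The quick brown fox\njumps over the lazy dog",
    "SEQ A B C D\nSEQ E F G H",
    "first line\nsecond line\nthird line",
    "contains 'quotes' and \"both\" kinds\non two lines",
]
_COMMENT_POOL = [" entry information", " generated fixture", " loop follows",
                 " residues studied in this work", ""]

_RESIDUE_ATOMS = {
    "ALA": ["N", "H", "CA", "HA", "CB", "C"],
    "GLY": ["N", "H", "CA", "C"],
    "SER": ["N", "H", "CA", "CB", "C"],
    "GLU": ["N", "H", "CA", "CB", "CG", "C"],
    "THR": ["N", "H", "CA", "CB", "CG2", "C"],
    "LEU": ["N", "H", "CA", "CB", "CG", "CD1", "CD2", "C"],
    "LYS": ["N", "H", "CA", "CB", "CG", "CD", "CE", "C"],
    "PHE": ["N", "H", "CA", "CB", "CG", "CD1", "C"],
}

V31_SHIFT_FIELDS = [
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Seq_ID",
    "_Atom_chem_shift.Comp_index_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Atom_type",
    "_Atom_chem_shift.Val",
    "_Atom_chem_shift.Val_err",
    "_Atom_chem_shift.Ambiguity_code",
]
V21_SHIFT_FIELDS = [
    "_Atom_shift_assign_ID",
    "_Residue_seq_code",
    "_Residue_label",
    "_Atom_name",
    "_Atom_type",
    "_Chem_shift_value",
    "_Chem_shift_value_error",
    "_Chem_shift_ambiguity_code",
]


def _shift_value(rng: random.Random, atom: str) -> str:
    element = atom[0]
    if element == "H":
        return f"{rng.uniform(0.5, 10.0):.2f}"
    if element == "N":
        return f"{rng.uniform(105.0, 135.0):.2f}"
    if atom == "C":
        return f"{rng.uniform(170.0, 182.0):.2f}"
    return f"{rng.uniform(10.0, 75.0):.2f}"


def _shift_composition(seed: int) -> list:
    """Residue/atom composition shared by the 2.1 and 3.1 shift renderings.

    Keyed only on the fixture seed so that fixtures differing in other flags
    still agree on the composition.
    """
    rng = random.Random((seed ^ 0x5A17) & 0x7FFFFFFF)
    residues = []
    for position in range(1, rng.randint(3, 7) + 1):
        rtype = rng.choice(sorted(_RESIDUE_ATOMS))
        atoms = [
            (atom, _shift_value(rng, atom), f"0.0{rng.randint(1, 9)}")
            for atom in _RESIDUE_ATOMS[rtype]
        ]
        residues.append((position, rtype, atoms))
    return residues


# ---------------------------------------------------------------------------
# structure construction (format-independent ground truth)
# ---------------------------------------------------------------------------

def _pick_value(rng: random.Random, flags: frozenset) -> str:
    roll = rng.random()
    if roll < 0.55:
        return rng.choice(_SIMPLE_VALUES)
    if roll < 0.75:
        return rng.choice(_SPACED_VALUES)
    if roll < 0.85 and "QUOTES_IN_VALUES" in flags:
        return rng.choice(_QUOTEY_VALUES)
    if roll < 0.92:
        return rng.choice(_TRICKY_VALUES)
    return rng.choice(_MULTILINE_VALUES)


def _pick_record_value(rng: random.Random, flags: frozenset) -> str:
    roll = rng.random()
    if roll < 0.8:
        return rng.choice(_SIMPLE_VALUES)
    if roll < 0.9:
        return rng.choice(_SPACED_VALUES)
    if roll < 0.95 and "QUOTES_IN_VALUES" in flags:
        return rng.choice(_QUOTEY_VALUES)
    if roll < 0.98:
        return rng.choice(_TRICKY_VALUES)
    return rng.choice(_MULTILINE_VALUES)


def _make_loop(rng: random.Random, spec: FixtureSpec, flags: frozenset,
               tag_prefix: str, empty: bool = False) -> tuple:
    n_fields = rng.randint(*spec.fields_per_loop)
    fields = [
        f"_{tag_prefix}.{rng.choice(_FIELD_WORDS)}_{j}" for j in range(n_fields)
    ]
    n_records = 0 if empty else rng.randint(*spec.records_per_loop)
    records = [
        [_pick_record_value(rng, flags) for _ in fields] for _ in range(n_records)
    ]
    return ("loop", fields, records)


def _shift_frame(name: str, version: str, composition: list) -> tuple:
    records = []
    counter = 1
    for position, rtype, atoms in composition:
        for atom, value, err in atoms:
            if version == "3.1":
                records.append([str(counter), str(position), str(position), rtype,
                                atom, atom[0], value, err, "1"])
            else:
                records.append([str(counter), str(position), rtype, atom,
                                atom[0], value, err, "1"])
            counter += 1
    fields = V31_SHIFT_FIELDS if version == "3.1" else V21_SHIFT_FIELDS
    category_tag = (
        ("_Assigned_chem_shift_list.Sf_category", "assigned_chemical_shifts")
        if version == "3.1"
        else ("_Saveframe_category", "assigned_chemical_shifts")
    )
    return ("frame", name, [("tag",) + category_tag, ("loop", fields, records)])


def _build_structure(spec: FixtureSpec) -> dict:
    rng = random.Random(spec.seed & 0x7FFFFFFF)
    flags = frozenset(spec.edge_flags)
    structure = {
        "id": str(rng.randint(10000, 99999)),
        "items": [],
        "trailing": None,
        "flags": sorted(flags),
        "shift_composition": None,
    }
    items = structure["items"]

    if "COMMENTS" in flags:
        items.append(("comment", rng.choice(_COMMENT_POOL)))

    for i in range(spec.n_saveframes):
        name = f"{rng.choice(_FRAME_WORDS)}_{i}"
        frame_items: list = []
        for t in range(rng.randint(1, 4)):
            key = f"_{rng.choice(_TAG_WORDS)}_{t}"
            frame_items.append(("tag", key, _pick_value(rng, flags)))
        if "COMMENTS" in flags and rng.random() < 0.5:
            frame_items.append(("comment", rng.choice(_COMMENT_POOL)))
        for l in range(rng.randint(*spec.loops_per_saveframe)):
            frame_items.append(_make_loop(rng, spec, flags, f"T{i}_{l}"))
        items.append(("frame", name, frame_items))

    def frame_of(index: int) -> list:
        return items[index][2]

    frame_indices = [i for i, item in enumerate(items) if item[0] == "frame"]
    if "EMBEDDED_SEMICOLON" in flags and frame_indices:
        frame_of(rng.choice(frame_indices)).append(
            ("tag", "_Details_with_semicolon",
             "Helix is ;near the C-term\nand continues ; further on")
        )
    if "QUOTES_IN_VALUES" in flags and frame_indices:
        target = frame_of(rng.choice(frame_indices))
        target.append(("tag", "_Quoted_detail_a", rng.choice(_QUOTEY_VALUES)))
        target.append(("tag", "_Quoted_detail_b", rng.choice(_QUOTEY_VALUES)))
    if "EMPTY_LOOP" in flags and frame_indices:
        frame_of(rng.choice(frame_indices)).append(
            _make_loop(rng, spec, flags, "Empty", empty=True)
        )
    if "MULTILINE_THEN_LOOP" in flags and frame_indices:
        _, glue_fields, glue_records = _make_loop(
            rng,
            FixtureSpec(fields_per_loop=(1, 3), records_per_loop=(1, 3)),
            frozenset(), "Glued",
        )
        frame_of(rng.choice(frame_indices)).append(
            ("glued", "_Sequence_one_letter",
             "MKVLAT GQTTV\nAKELGI DPTTA", glue_fields, glue_records)
        )

    if "V21_SHIFTS" in flags or "V31_SHIFTS" in flags:
        composition = _shift_composition(spec.seed)
        structure["shift_composition"] = [
            [position, rtype, [[atom, value] for atom, value, _ in atoms]]
            for position, rtype, atoms in composition
        ]
        k = 1
        if "V21_SHIFTS" in flags:
            items.append(_shift_frame(f"assigned_chem_shift_list_{k}", "2.1",
                                      composition))
            k += 1
        if "V31_SHIFTS" in flags:
            items.append(_shift_frame(f"assigned_chem_shift_list_{k}", "3.1",
                                      composition))

    if "MULTILINE_NO_TRAILING_NEWLINE" in flags:
        structure["trailing"] = (
            "_Final_remark", "last block of the file\nwith no trailing newline"
        )
    return structure


def _iter_frame_entries(frame_items):
    """Yield (key, value_or_Loop) pairs for frame items, numbering loops."""
    n_loops = 0
    for item in frame_items:
        kind = item[0]
        if kind == "tag":
            yield item[1], item[2]
        elif kind == "loop":
            yield f"loop_{n_loops}", Loop(list(item[1]),
                                          [dict(zip(item[1], r)) for r in item[2]])
            n_loops += 1
        elif kind == "glued":
            yield item[1], item[2]
            yield f"loop_{n_loops}", Loop(list(item[3]),
                                          [dict(zip(item[3], r)) for r in item[4]])
            n_loops += 1
        # comments: excluded from the canonical (capture-off) view


def _structure_to_entry(structure: dict) -> StarEntry:
    entry = StarEntry()
    entry["data"] = structure["id"]
    n_loops = 0
    for item in structure["items"]:
        if item[0] == "frame":
            frame = Saveframe()
            for key, value in _iter_frame_entries(item[2]):
                frame[key] = value
            entry[item[1]] = frame
        elif item[0] == "tag":
            entry[item[1]] = item[2]
        elif item[0] == "loop":
            entry[f"loop_{n_loops}"] = Loop(
                list(item[1]), [dict(zip(item[1], r)) for r in item[2]]
            )
            n_loops += 1
    if structure["trailing"] is not None:
        key, value = structure["trailing"]
        entry[key] = value
    return entry


def _manifest(structure: dict, fmt: str) -> dict:
    entry = _structure_to_entry(structure)
    flat_keys = []
    loops = []
    n_records = 0
    n_values = 0
    n_comments = sum(
        1 for item in structure["items"] if item[0] == "comment"
    ) + sum(
        1
        for item in structure["items"]
        if item[0] == "frame"
        for inner in item[2]
        if inner[0] == "comment"
    )
    n_frames = 0
    for key, value in entry.items():
        flat_keys.append(key)
        if isinstance(value, Loop):
            loops.append({"path": key, "n_fields": len(value.fields),
                          "n_records": len(value.records)})
            n_records += len(value.records)
            n_values += len(value.fields) * len(value.records)
        elif isinstance(value, Saveframe):
            n_frames += 1
            for inner_key, inner in value.items():
                flat_keys.append(f"{key}/{inner_key}")
                if isinstance(inner, Loop):
                    loops.append({"path": f"{key}/{inner_key}",
                                  "n_fields": len(inner.fields),
                                  "n_records": len(inner.records)})
                    n_records += len(inner.records)
                    n_values += len(inner.fields) * len(inner.records)
                else:
                    n_values += 1
        elif key != "data":
            n_values += 1
    return {
        "format": fmt,
        "data_id": structure["id"],
        "edge_flags": structure["flags"],
        "n_saveframes": n_frames,
        "n_loops": len(loops),
        "n_records": n_records,
        "n_values": n_values,
        "n_comments": n_comments,
        "flat_keys": flat_keys,
        "loops": loops,
        "shift_composition": structure["shift_composition"],
    }


# ---------------------------------------------------------------------------
# NMR-STAR text rendering (independent of nmrstar.writer)
# ---------------------------------------------------------------------------

def _keywordish(value: str) -> bool:
    lowered = value.lower()
    return lowered in ("loop_", "stop_", "save_") or lowered.startswith(
        ("data_", "save_")
    )


def _render_scalar(value: str, rng: random.Random) -> str | None:
    """Inline encoding of a value, or None when block form is required."""
    if "\n" in value or ("'" in value and '"' in value):
        return None
    bare_ok = (
        value != ""
        and not any(c in " \t" for c in value)
        and "'" not in value
        and '"' not in value
        and value[0] not in "_#;"
        and not _keywordish(value)
    )
    if bare_ok and rng.random() < 0.85:
        return value
    if "'" not in value:
        return f"'{value}'"
    return f'"{value}"'


def _render_block(key_line: str, value: str, out: list) -> None:
    out.append(f"{key_line}\n;\n{value}\n;\n")


def _render_loop(fields, records, rng: random.Random, out: list,
                 header: bool = True) -> None:
    if header:
        out.append("loop_\n")
    indent = " " * rng.randint(2, 5)
    for field_name in fields:
        out.append(f"{indent}{field_name}\n")
    for record in records:
        parts: list = []
        for value in record:
            fragment = _render_scalar(value, rng)
            if fragment is None:
                if parts:
                    out.append(" ".join(parts))
                    parts = []
                    out.append(f"\n;\n{value}\n;\n")
                else:
                    out.append(f";\n{value}\n;\n")
            else:
                parts.append(fragment)
        if parts:
            out.append(" ".join(parts) + "\n")
    out.append("stop_\n")


def _render_star(structure: dict, rng: random.Random) -> str:
    out: list = [f"data_{structure['id']}\n"]

    def render_items(items) -> None:
        for item in items:
            kind = item[0]
            if kind == "tag":
                fragment = _render_scalar(item[2], rng)
                if fragment is None:
                    _render_block(item[1], item[2], out)
                else:
                    out.append(f"{item[1]} {fragment}\n")
            elif kind == "comment":
                out.append(f"#{item[1]}\n")
            elif kind == "loop":
                _render_loop(item[1], item[2], rng, out)
            elif kind == "glued":
                # closing ";" immediately followed by loop_ on the same line
                out.append(f"{item[1]}\n;\n{item[2]}\n;loop_\n")
                _render_loop(item[3], item[4], rng, out, header=False)

    for item in structure["items"]:
        kind = item[0]
        if kind == "frame":
            if rng.random() < 0.5:
                out.append("\n")
            out.append(f"save_{item[1]}\n")
            render_items(item[2])
            out.append("save_\n")
        else:
            render_items([item])

    if structure["trailing"] is not None:
        key, value = structure["trailing"]
        out.append(f"{key}\n;\n{value}\n;")  # deliberately no final newline
    return "".join(out)


def _render_json(structure: dict) -> str:
    entry = _structure_to_entry(structure)

    def jsonable(node):
        if isinstance(node, Loop):
            return [list(node.fields), [dict(r) for r in node.records]]
        if isinstance(node, dict):
            return {k: jsonable(v) for k, v in node.items()}
        return node

    return json.dumps(jsonable(entry), ensure_ascii=False)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def generate_entry(spec: FixtureSpec, fmt: str = "nmrstar") -> tuple[str, dict]:
    """Return ``(document text, manifest)`` for a fixture spec.

    ``fmt`` selects the rendering: ``"nmrstar"`` (default) or ``"json"``.
    The manifest records the data id, exact counts (saveframes, loops,
    records, values, comments), the flattened key order, per-loop
    dimensions, the shift composition (when shift flags are set) and the
    enabled edge flags.
    """
    structure = _build_structure(spec)
    manifest = _manifest(structure, fmt)
    if fmt == "json":
        text = _render_json(structure)
    elif fmt == "nmrstar":
        text = _render_star(structure, random.Random((spec.seed + 7919) & 0x7FFFFFFF))
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    return text, manifest


def expected_entry(spec: FixtureSpec) -> StarEntry:
    """The ground-truth :class:`StarEntry` a capture-off parse should produce."""
    return _structure_to_entry(_build_structure(spec))


def _corpus_spec(seed: int, index: int) -> FixtureSpec:
    child = (seed * 1_000_003 + index) & 0x7FFFFFFF
    rng = random.Random(child ^ 0x0BAD5EED)
    flags = {flag for flag in EDGE_FLAGS if rng.random() < 0.35}
    if index < len(EDGE_FLAGS):  # guarantee coverage even for tiny corpora
        flags.add(EDGE_FLAGS[index])
    return FixtureSpec(seed=child, edge_flags=frozenset(flags))


def iter_corpus(n: int, seed: int, fmt: str = "nmrstar"):
    """Lazily yield ``(name, text, manifest)`` for a corpus of ``n`` fixtures.

    ``fmt="mixed"`` draws each member's format (NMR-STAR or JSONized)
    pseudo-randomly; extensions are ``.str`` / ``.json`` accordingly.
    """
    for index in range(n):
        spec = _corpus_spec(seed, index)
        if fmt == "mixed":
            member_fmt = "json" if random.Random(spec.seed ^ 0x3F).random() < 0.5 else "nmrstar"
        else:
            member_fmt = fmt
        text, manifest = generate_entry(spec, fmt=member_fmt)
        extension = "json" if member_fmt == "json" else "str"
        yield f"fixture_{index:05d}.{extension}", text, manifest


def generate_corpus(n: int, seed: int, out: str | Path, fmt: str = "nmrstar") -> dict:
    """Write ``n`` fixtures to a directory or archive; return the manifest index.

    ``out`` ending in ``.zip``, ``.tar``, ``.tar.gz``/``.tgz`` or
    ``.tar.bz2``/``.tbz2`` packs the fixtures into an archive of that kind;
    any other path is treated as a directory. The machine-readable manifest
    index is written next to the target as ``<out>.manifest.json`` (never
    inside it, so the target contains fixtures only).
    """
    out = Path(out)
    index = {"n": n, "seed": seed, "format": fmt, "members": []}
    name = out.name.lower()

    def members():
        for member_name, text, manifest in iter_corpus(n, seed, fmt):
            index["members"].append({"name": member_name, "manifest": manifest})
            yield member_name, text

    out.parent.mkdir(parents=True, exist_ok=True)
    if name.endswith(".zip"):
        with zipfile.ZipFile(out, "w", compression=zipfile.ZIP_DEFLATED) as archive:
            for member_name, text in members():
                archive.writestr(member_name, text)
    elif name.endswith((".tar", ".tar.gz", ".tgz", ".tar.bz2", ".tbz2")):
        mode = "w"
        if name.endswith((".tar.gz", ".tgz")):
            mode = "w:gz"
        elif name.endswith((".tar.bz2", ".tbz2")):
            mode = "w:bz2"
        with tarfile.open(out, mode) as archive:
            for member_name, text in members():
                data = text.encode("utf-8")
                info = tarfile.TarInfo(member_name)
                info.size = len(data)
                archive.addfile(info, io.BytesIO(data))
    else:
        out.mkdir(parents=True, exist_ok=True)
        for member_name, text in members():
            (out / member_name).write_text(text, encoding="utf-8")

    manifest_path = out.parent / (out.name + ".manifest.json")
    manifest_path.write_text(json.dumps(index), encoding="utf-8")
    return index


# ---------------------------------------------------------------------------
# raw-document fuzzing for the tokenizer
# ---------------------------------------------------------------------------

_FUZZ_WORDS = ["data_18569", "data_X", "save_shifts", "save_", "loop_", "stop_",
               "_Atom_chem_shift.Val", "_T", "12.5", ".", "?", "$frame_ref",
               "word", "don't", "a#b", "x;y", "STOP_", "Loop_", "Data_9"]
_FUZZ_QUOTED = ["it's ok", "a;b", "x # y", "tail'", 'say "hi"', "", "two  words",
                "ends with q'"]
_FUZZ_MULTILINE = ["plain text", "with ; inner semicolon", "two\nlines",
                   "quote ' and \" inside", "", "ends with space ",
                   "# looks like comment", "inline-start"]
_FUZZ_COMMENTS = [" a comment", "", " with ; and ' chars", "#doubled"]
_FUZZ_WS = [" ", "  ", "\t", "\n", "\n\n", " \t ", "\n "]


def random_document(rng: random.Random) -> str:
    """A random lexically valid NMR-STAR token soup for differential testing.

    Exercises every token class, quoting form and the glued-after-multiline
    cases; intended for comparing the production tokenizer against an
    independent reference automaton.
    """
    parts: list = []
    at_line_start = True

    def emit(text: str) -> None:
        nonlocal at_line_start
        parts.append(text)
        at_line_start = text.endswith("\n")

    for _ in range(rng.randint(3, 25)):
        roll = rng.random()
        if roll < 0.45:
            emit(rng.choice(_FUZZ_WORDS))
            emit(rng.choice(_FUZZ_WS))
        elif roll < 0.6:
            quote = rng.choice("'\"")
            content = rng.choice(_FUZZ_QUOTED)
            if quote in content and (f"{quote} " in content or content == quote):
                content = content.replace(quote, "*")
            emit(f"{quote}{content}{quote}")
            emit(rng.choice(_FUZZ_WS))
        elif roll < 0.75:
            if not at_line_start:
                emit("\n")
            content = rng.choice(_FUZZ_MULTILINE)
            opener = ";" if rng.random() < 0.7 else ";" + content.split("\n")[0]
            body = content if opener == ";" else "\n".join(content.split("\n")[1:])
            emit(opener + "\n" + (body + "\n" if body else "") + ";")
            if rng.random() < 0.4:  # glue the next token to the closing ";"
                emit(rng.choice(["loop_", "stop_", "save_", "_T", "word"]))
            emit(rng.choice(_FUZZ_WS))
        elif roll < 0.85:
            emit("#" + rng.choice(_FUZZ_COMMENTS))
            emit("\n")
        else:
            emit(rng.choice(_FUZZ_WS))
    return "".join(parts)
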