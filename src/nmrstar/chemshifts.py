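"""Extraction and visualization of assigned chemical shifts.

A BMRB entry stores its assigned chemical shifts — the resonance frequency
offsets, in ppm, of individual atoms — in a loop whose tag schema differs
between NMR-STAR versions. Version 3.1 uses ``_Atom_chem_shift.Seq_ID`` /
``Comp_ID`` / ``Atom_ID`` / ``Val``; version 2.1 uses ``_Residue_seq_code``
/ ``_Residue_label`` / ``_Atom_name`` / ``_Chem_shift_value``. Discovery
keys off these loop field schemas rather than saveframe category tags,
because category tag names differ across versions and legacy files often
mislabel them.

:func:`extract_shifts` normalises either schema into a
:class:`ChemShiftTable` organised chain → residue → atom (one chain per
shift loop, residues ordered by sequence position); :func:`filter_shifts`
restricts it to chosen residue types and atom names; :func:`render_graph`
emits the table as a DOT-language tree (root = entry id, then chains,
residue nodes labelled ``<Type><Position>``, and one ``<atom>: <value>``
leaf per shift), optionally rendered to PNG/PDF/SVG through an external
``dot`` layout engine when one is installed.

Shift values stay strings for display fidelity; they are only validated as
parseable decimals, with a warning on failure. Ambiguity codes and error
columns are ignored for visualization.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .exceptions import MissingShiftDataError
from .model import Loop, StarEntry

__all__ = [
    "Residue",
    "Chain",
    "ChemShiftTable",
    "extract_shifts",
    "filter_shifts",
    "render_graph",
]

log = logging.getLogger(__name__)

V31_SCHEMA = frozenset(
    {
        "_Atom_chem_shift.Seq_ID",
        "_Atom_chem_shift.Comp_ID",
        "_Atom_chem_shift.Atom_ID",
        "_Atom_chem_shift.Val",
    }
)
V21_SCHEMA = frozenset(
    {"_Residue_seq_code", "_Residue_label", "_Atom_name", "_Chem_shift_value"}
)


@dataclass
class Residue:
    position: int
    type: str  # 3-letter amino-acid code
    atoms: list = field(default_factory=list)  # ordered (atom name, value string)


@dataclass
class Chain:
    label: str
    residues: list = field(default_factory=list)


@dataclass
class ChemShiftTable:
    entry_id: str
    chains: list = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def _loop_to_chain(loop: Loop, label: str, columns: tuple[str, str, str, str]) -> Chain:
    seq_tag, comp_tag, atom_tag, val_tag = columns
    by_position: dict[int, Residue] = {}
    for record in loop.records:
        try:
            position = int(record[seq_tag])
        except ValueError:
            log.warning("chain %s: non-integer sequence position %r", label, record[seq_tag])
            continue
        residue = by_position.get(position)
        if residue is None:
            residue = by_position[position] = Residue(position, record[comp_tag])
        atom = record[atom_tag]
        value = record[val_tag]
        try:
            float(value)
        except ValueError:
            log.warning("chain %s %s%d %s: shift value %r is not a decimal",
                        label, residue.type, position, atom, value)
        if any(name == atom for name, _ in residue.atoms):
            log.warning("chain %s %s%d: duplicate atom %s; keeping first",
                        label, residue.type, position, atom)
            continue
        residue.atoms.append((atom, value))
    return Chain(label, [by_position[p] for p in sorted(by_position)])


def _iter_loops(entry: StarEntry):
    for value in entry.values():
        if isinstance(value, Loop):
            yield value
        elif isinstance(value, Mapping):
            for inner in value.values():
                if isinstance(inner, Loop):
                    yield inner


def extract_shifts(entry: StarEntry) -> ChemShiftTable:
    """Normalise every assigned-chemical-shift loop of ``entry`` into a table.

    Shift loops are located by field schema (v3.1 first, then v2.1) in
    document order; each loop becomes one chain, labelled ordinally. Raises
    :class:`MissingShiftDataError` when no shift loop exists.
    """
    table = ChemShiftTable(entry_id=entry.get("data", ""))
    for loop in _iter_loops(entry):
        fields = set(loop.fields)
        label = str(len(table.chains) + 1)
        if V31_SCHEMA <= fields:
            table.chains.append(
                _loop_to_chain(
                    loop,
                    label,
                    (
                        "_Atom_chem_shift.Seq_ID",
                        "_Atom_chem_shift.Comp_ID",
                        "_Atom_chem_shift.Atom_ID",
                        "_Atom_chem_shift.Val",
                    ),
                )
            )
        elif V21_SCHEMA <= fields:
            table.chains.append(
                _loop_to_chain(
                    loop,
                    label,
                    ("_Residue_seq_code", "_Residue_label", "_Atom_name", "_Chem_shift_value"),
                )
            )
    if not table.chains:
        raise MissingShiftDataError(
            "no assigned chemical shift loop found (searched the NMR-STAR 3.1 "
            "_Atom_chem_shift.* schema and the 2.1 _Residue_seq_code/"
            "_Residue_label/_Atom_name/_Chem_shift_value schema)"
        )
    return table


def filter_shifts(table: ChemShiftTable, aminoacids=None, atoms=None) -> ChemShiftTable:
    """Return a new table restricted to the given residue types and atom names.

    ``None`` or an empty collection means "keep all" for that filter. Order
    is preserved; residues passing the residue filter are kept even when the
    atom filter leaves them with no atoms.
    """
    aminoacids = set(aminoacids) if aminoacids else None
    atoms = set(atoms) if atoms else None
    chains = []
    for chain in table.chains:
        residues = []
        for residue in chain.residues:
            if aminoacids is not None and residue.type not in aminoacids:
                continue
            kept = [
                (name, value)
                for name, value in residue.atoms
                if atoms is None or name in atoms
            ]
            residues.append(Residue(residue.position, residue.type, kept))
        chains.append(Chain(chain.label, residues))
    return ChemShiftTable(table.entry_id, chains)


def _dot_escape(label: str) -> str:
    return label.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(table: ChemShiftTable) -> str:
    """Return the DOT-language tree for a table.

    Node count is exactly 1 (root) + #chains + #residues + #atoms.
    """
    lines = ["digraph chemical_shifts {", "    node [shape=box];"]
    counter = 0

    def node(label: str) -> str:
        nonlocal counter
        name = f"n{counter}"
        counter += 1
        lines.append(f'    {name} [label="{_dot_escape(label)}"];')
        return name

    root = node(table.entry_id or "entry")
    for chain in table.chains:
        chain_node = node(f"chain {chain.label}")
        lines.append(f"    {root} -> {chain_node};")
        for residue in chain.residues:
            residue_node = node(f"{residue.type}{residue.position}")
            lines.append(f"    {chain_node} -> {residue_node};")
            for atom, value in residue.atoms:
                leaf = node(f"{atom}: {value}")
                lines.append(f"    {residue_node} -> {leaf};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_graph(table: ChemShiftTable, out_path, image_format: str = "dot") -> Path:
    """Write the table as a graph document; return the path actually written.

    ``image_format="dot"`` writes DOT text directly. For ``png``/``pdf``/
    ``svg`` an external ``dot`` layout engine is invoked when available;
    otherwise the DOT file is written instead, with a warning.
    """
    if image_format not in ("dot", "png", "pdf", "svg"):
        raise ValueError(f"unsupported image format {image_format!r}")
    if not table.chains or table.n_residues == 0:
        raise ValueError("chemical shift table is empty; nothing to render")
    out_path = Path(out_path)
    dot_text = to_dot(table)
    if image_format == "dot":
        out_path.write_text(dot_text, encoding="utf-8")
        return out_path
    engine = shutil.which("dot")
    if engine is None:
        fallback = out_path.with_suffix(".dot")
        log.warning(
            "graph layout engine 'dot' not found; writing DOT text to %s instead",
            fallback,
        )
        fallback.write_text(dot_text, encoding="utf-8")
        return fallback
    with tempfile.NamedTemporaryFile("w", suffix=".dot", delete=False) as handle:
        handle.write(dot_text)
        tmp = handle.name
    try:
        subprocess.run(
            [engine, f"-T{image_format}", "-o", str(out_path), tmp], check=True
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    return out_path
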