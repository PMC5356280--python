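# nmrstar

A lossless parsing stack for the NMR-STAR flat-file format of the
Biological Magnetic Resonance Data Bank (BMRB), the public repository of
NMR spectroscopic data on biomolecules. BMRB entries are distributed as
NMR-STAR text (versions 2.1 and 3.1): a `data_<id>` block containing named
saveframes (`save_<name>` … `save_`), free tag/value pairs and loops
(`loop_` … `stop_`) — tables of records given as field tags followed by
row-major values. The format is human readable, but entry sizes make an
explicit in-memory representation a practical requirement for systematic
analysis.

The package is for structural biologists and bioinformaticians who need
programmatic access to BMRB data: it tokenizes and parses NMR-STAR into
insertion-ordered nested mappings, writes them back, converts them
losslessly to and from an equivalent JSON representation (usable from any
language with a JSON parser), streams entries from files, directories,
zip/tar archives, URLs or BMRB ids, and extracts and visualizes assigned
chemical shifts (the per-atom resonance offsets, in ppm, that are the
primary assigned experimental quantity in BMRB entries).

## Model

A parsed entry is an ordered mapping

```
StarEntry
├── "data"            → data-block identifier
└── <saveframe name>  → Saveframe (ordered mapping)
    ├── "_Tag"        → value string
    └── "loop_N"      → Loop = (fields [_f1.._fk], records [{_f1: v, …}, …])
```

with every value kept verbatim as a string (including the `.` / `?`
null/unknown placeholders and `$framecode` references) — no coercion, which
is what makes `parse → write → parse` and `parse → JSON → parse` exact:
both round trips are structurally equal (same key sequences at every level,
same value strings) for every document. Loops map to JSON as
`[[fields…], [records…]]`; saveframes as nested objects in document order.

The tokenizer handles the multiline cases that break regex-based parsers:
semicolon-delimited blocks containing interior semicolons, blocks whose
closing `;` is the last byte of the file, and blocks whose closing `;` is
immediately followed by `loop_`.

## Worked example

The bundled generator writes fully synthetic entries (real BMRB files work
identically — `read_entries` also accepts URLs and bare BMRB ids):

```python
import nmrstar
from nmrstar.fixtures import FixtureSpec, generate_entry

text, _ = generate_entry(FixtureSpec(seed=18569, edge_flags={"V31_SHIFTS"}))
open("bmr18569.str", "w").write(text)

entry = next(nmrstar.read_entries("bmr18569.str"))
print(entry["data"])
shifts = nmrstar.extract_shifts(entry)
ca = [(r.type, r.position, dict(r.atoms).get("CA"))
      for chain in shifts.chains for r in chain.residues]
print(ca[:3])
print(nmrstar.to_json_text(entry)[:60])
```

prints

```
38510
[('GLY', 1, '21.08'), ('ALA', 2, '12.24'), ('THR', 3, '66.02')]
{"data": "38510", "spectrometer_0": {"_Name_0": "0.0071", "_
```

— the data-block id, each residue's CA chemical shift in ppm (strings,
exactly as deposited), and the head of the JSONized form.

From the shell:

```sh
nmrstar convert bmr18569.str 18569.json --from_format=nmrstar --to_format=json
nmrstar convert 18569.json bmr18569.str --from_format=json --to_format=nmrstar
nmrstar csview bmr18569.str --aminoacids=GLU,THR --atoms=CA,CB,CG,CG2 \
        --csview_outfile=18569_cs_GLU_THR --csview_format=dot
```

`convert` prints `converted 1/1 (0 failed)` and exits 0; directories and
zip/tar archives convert many-to-many with member structure preserved.
`csview` writes a residue-organized tree (entry → chain → residue →
`atom: shift` leaves) in DOT format; PNG/PDF/SVG are produced when a
`dot` layout engine is installed.

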