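# Methods

## The format and the representation

NMR-STAR is a STAR-family flat-file database: one `data_<id>` block holding
named saveframes, each an ordered collection of tag/value pairs and loops
(tables given as field tags followed by row-major values, closed by
`stop_`). The two active dialects, 2.1 and 3.1, share this grammar and
differ in tag vocabulary and layout. The package's contract is *lossless
structural representation*: an entry is an insertion-ordered nested mapping
in which every scalar is the exact deposited string. `.` and `?`
(null/unknown placeholders) and `$framecode` references are ordinary values
kept verbatim — any coercion to `None`/floats would make the NMR-STAR ↔
model ↔ JSON triangle lossy. Equality between entries
(`structurally_equal`) is order-sensitive at every nesting level and
ignores only the provenance descriptor.

Tags and loops appearing at data-block level (legal STAR, occasionally seen
in the wild) are stored directly in the entry body. A file with several
`data_` blocks is parsed to its first block with a warning; multi-block
files do not occur in BMRB distribution and supporting them would change
the top-level type for everyone.

## Lexical analysis

The tokenizer is a single-pass state machine over the decoded text
(UTF-8; undecodable bytes are replaced with a logged warning rather than
aborting, since legacy entries contain stray bytes; CRLF is normalised to
LF before any column-1 test). The rules that matter in practice:

* a quote closes a quoted value only when immediately followed by
  whitespace or end-of-line, so `'it's fine'` is one value — apostrophes
  inside words are content;
* a `;` in column 1 opens/closes a multiline block; semicolons anywhere
  else are content, which is exactly the case that defeats regex-based
  multiline collapsing;
* the closing `;` may be the last byte of the file, and the remainder of
  its line is ordinary token stream, so `;loop_` is a block terminator
  followed by a loop;
* `#` starts a comment only at the start of a whitespace-delimited
  position; `#` inside any value is content;
* keywords match case-insensitively and are always written lowercase.

Multiline content semantics (the grammar leaves this open): content begins
after the opening `;`, with exactly one following newline skipped when
present, and ends before the newline preceding the closing `;`. This is
canonical for this package; the writer always emits `;\n…\n;\n`, so the
convention is invisible to round trips.

Each character is touched a bounded constant number of times (≤ 3 N,
asserted by an instrumented test), so tokenization is strictly linear; the
whole stack streams — the parser pulls tokens through a cursor and never
materialises a token list, and the multi-source reader holds at most one
document text and one entry at a time (instrumented with weak references in
the archive-conversion test).

## Parsing policies

Strict mode (default) refuses anything that cannot be represented
losslessly: duplicate tags or saveframe names, values without a preceding
tag, loops without fields or with a value count not divisible by the field
count, and a loop terminated by `save_` rather than `stop_`. Lenient mode
applies the conventional repairs (keep first occurrence, skip stray values,
truncate a ragged final record, accept the historical missing-`stop_`
idiom) and logs each one. Empty loops (fields, no records) are legal in
both modes with a warning. Comment capture is off by default; when on,
comments become `comment_N` keys at the level where they occur. Comments
inside a loop body have no slot in a (fields, records) pair and are
discarded with a debug message — a deliberate trade against complicating
the loop type.

## Writing and quoting

The writer emits one tag/value per line, indented loop field names, one
record per line, and chooses the minimal safe encoding per value: bare if
the value has no whitespace or quotes, does not start with `_ # $ ;`, is
not keyword-like and is non-empty; otherwise single- then double-quoted
(never for values with newlines); otherwise a semicolon block. Keyword
lookalikes (`loop_`, `stop_`, `save_x`, `data_x`) are always quoted so they
cannot re-lex as structure; an empty value is written `''`. One class of
strings is genuinely unrepresentable in STAR: a value containing a line
that itself begins with `;` would terminate its own block, and the grammar
has no escape. `format_value` raises `UnrepresentableValueError` for these
(the encode/decode property test verifies exactly this boundary). Output is
not byte-identical to the input — column alignment and quoting style are
normalised — because the round-trip contract is structural, not
typographic.

## JSON mapping

Saveframes map to JSON objects in document order, loops to two-element
arrays `[fields, records]`, scalars to strings; the data-block id lives
under the reserved first key `"data"`. Member order is significant on both
ends; the standard-library `json` module preserves it because Python dicts
are insertion-ordered. Compact output is the default (JSONized NMR-STAR is
already more verbose than the original), `indent=4` optional. XML was not
considered: it has no one-to-one mapping onto nested mappings/lists.

## Sources and streaming

`make_spec` infers what a string names with deterministic precedence:
existing local path (directory, archive by extension, else file) → URL
scheme → all-digits BMRB id. Archives (zip, tar, tar.gz, tar.bz2) stream
member-by-member without extraction; directories are walked recursively in
sorted order, skipping hidden files and non-text extensions unless a glob
is given. BMRB ids are substituted into configurable URL templates
(`nmrstar.sources.config`), one per format version, chosen explicitly by
the caller — endpoint URLs change and an id alone does not determine the
version. The test suite exercises the mechanism only through `file://`
templates; no test touches the network.

## Chemical shifts

Shift loops are discovered by field schema — 3.1:
`_Atom_chem_shift.{Seq_ID, Comp_ID, Atom_ID, Val}`; 2.1:
`_Residue_seq_code`, `_Residue_label`, `_Atom_name`, `_Chem_shift_value` —
rather than saveframe category tags, which differ across versions and are
mislabelled in some legacy files. Each loop becomes one ordinally labelled
chain; residues are ordered by sequence position; duplicate atom names
within a residue keep the first occurrence with a warning. Values stay
strings (display fidelity) and are only validated as parseable decimals;
ambiguity codes and error columns are ignored for visualization. The DOT
tree has exactly 1 + chains + residues + atoms nodes (root, chain, residue
`<Type><Position>`, leaf `<atom>: <value>`); PNG/PDF/SVG are delegated to
an external `dot` layout engine when present, with a documented fallback to
writing the `.dot` file.

## Synthetic fixtures: what they emulate and what they do not

The generator emits documents with the full structural repertoire —
saveframes, data-block-level tags and loops, every quoting form, comments,
empty loops, the three documented multiline hard cases (interior semicolon;
closing `;` at end-of-file with no trailing newline; closing `;` glued to
`loop_`) — plus assigned-chemical-shift saveframes rendered in both the 2.1
and 3.1 schemas from one residue/atom composition drawn from a
sub-generator keyed only on the seed (so version-paired fixtures encode
identical shifts). Its text renderer is independent of the package's
writer and randomises its encoding choices, so round-trip tests cannot pass
by shared bugs. Value pools deliberately include keyword lookalikes,
leading `#`/`$`/`_`/`;` characters and quote mixtures to stress the
writer's quoting policy.

What the fixtures do not emulate: real BMRB tag vocabularies beyond the
shift loops, realistic shift-value distributions (values are uniform within
coarse per-element ranges), entry sizes (fixtures are a few KB; real 3.1
entries reach MBs), or real-world file damage. Passing the corpus therefore
demonstrates grammar coverage and lossless round-tripping, not schema-level
semantics.

Default corpus conditions: 1,000 documents per run, each fixture with 3
saveframes, 0–2 loops of 1–4 fields and 0–5 records per saveframe, each
edge flag enabled independently with probability 0.35 (≈ 350 occurrences
per flag per corpus; the first eight fixtures force one flag each so even
tiny corpora cover all flags). Differential lexer testing uses 10,000
randomized documents per run. These sizes give each edge case hundreds of
independent exercises while the whole acceptance battery completes in
seconds.

## Numerical and degenerate-input choices

There are no floating-point computations anywhere in the core — all
comparisons are exact string/structure equality, so no tolerances exist to
tune. Degenerate inputs: an empty document fails with "missing data_
header"; an empty directory yields an empty stream without error; an
empty-after-filter shift table is refused by the renderer with a message;
an empty string value round-trips as `''`.

## Known limitations

* CIF/mmCIF dialect features (bracket lists, triple quotes) are out of
  scope, though the lexer is structured to be extendable to them.
* No validation against the official NMR-STAR dictionary: tags are opaque
  strings, and recommended tag ordering when authoring entries from
  scratch is the user's responsibility.
* Single-block files only (first block kept, warning otherwise).
* A value containing a column-1 semicolon line cannot be serialized (STAR
  grammar limitation, raised explicitly).
* No parallel fetching, caching of remote entries, or FTP.
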