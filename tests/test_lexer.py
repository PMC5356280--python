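"""Tokenizer unit and differential tests."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from nmrstar import StarLexError, TokenKind, tokenize
from nmrstar.fixtures import random_document
from nmrstar.writer import format_value

from reference_lexer import RefLexError, as_triples, reference_tokenize


def kinds_texts(text, emit_comments=False):
    return [(t.kind, t.text) for t in tokenize(text, emit_comments)]


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("data_18569\n", [(TokenKind.DATA_HEADER, "18569")]),
        (
            ";\nHelix is ;near the C-term\n;\n",
            [(TokenKind.VALUE, "Helix is ;near the C-term")],
        ),
        (
            "'it's fine' x",
            [(TokenKind.VALUE, "it's fine"), (TokenKind.VALUE, "x")],
        ),
        (
            ";\ntext\n;loop_\n_T\nv\nstop_\n",
            [
                (TokenKind.VALUE, "text"),
                (TokenKind.LOOP_BEGIN, ""),
                (TokenKind.TAG, "_T"),
                (TokenKind.VALUE, "v"),
                (TokenKind.LOOP_END, ""),
            ],
        ),
        # closing ";" at end of file without a trailing newline
        (";\nfinal block\n;", [(TokenKind.VALUE, "final block")]),
        ("save_shifts save_", [(TokenKind.SAVE_BEGIN, "shifts"), (TokenKind.SAVE_END, "")]),
        ("DATA_9 LOOP_ STOP_", [
            (TokenKind.DATA_HEADER, "9"),
            (TokenKind.LOOP_BEGIN, ""),
            (TokenKind.LOOP_END, ""),
        ]),
        # null/unknown placeholders and framecodes stay verbatim values
        (". ? $sample_one", [
            (TokenKind.VALUE, "."),
            (TokenKind.VALUE, "?"),
            (TokenKind.VALUE, "$sample_one"),
        ]),
        # "#" inside a word or a quoted value is content, not a comment
        ("a#b '# quoted'", [(TokenKind.VALUE, "a#b"), (TokenKind.VALUE, "# quoted")]),
        # ";" not in column 1 is an ordinary word character
        ("x ;y", [(TokenKind.VALUE, "x"), (TokenKind.VALUE, ";y")]),
        ('"double \'single\'" end', [
            (TokenKind.VALUE, "double 'single'"),
            (TokenKind.VALUE, "end"),
        ]),
        ("", []),
        ("   \n\t \n", []),
    ],
)
def test_grammar_examples(text, expected):
    assert kinds_texts(text) == expected


def test_comments_emitted_only_on_request():
    text = "# leading note\ndata_1\n_T v # not a comment start\n"
    silent = kinds_texts(text)
    assert (TokenKind.COMMENT, " leading note") not in silent
    with_comments = kinds_texts(text, emit_comments=True)
    assert with_comments[0] == (TokenKind.COMMENT, " leading note")
    # "#" mid-line at a whitespace-delimited position does start a comment
    assert (TokenKind.COMMENT, " not a comment start") in with_comments


def test_crlf_normalized_before_column_detection():
    lf = ";\r\nblock line\r\n;\r\n_T v\r\n"
    assert kinds_texts(lf) == [
        (TokenKind.VALUE, "block line"),
        (TokenKind.TAG, "_T"),
        (TokenKind.VALUE, "v"),
    ]


def test_line_numbers_non_decreasing_and_correct():
    text = "data_1\n\n_T\n;\na\nb\n;\n_U v\n"
    tokens = list(tokenize(text))
    lines = [t.line for t in tokens]
    assert lines == sorted(lines)
    assert tokens[1].line == 3  # _T
    assert tokens[2].line == 4  # multiline opens on line 4
    assert tokens[3].line == 8  # _U


@pytest.mark.parametrize(
    ("text", "fragment"),
    [
        ("_T 'never closed\nmore", "line 1"),
        ("data_1\n;\nnever closed", "line 2"),
        ('"also open', "line 1"),
    ],
)
def test_unterminated_constructs_raise_with_line(text, fragment):
    with pytest.raises(StarLexError) as err:
        list(tokenize(text))
    assert fragment in str(err.value)


class CountingStr(str):
    """str that counts character accesses via indexing and slicing."""

    def __new__(cls, value):
        self = super().__new__(cls, value)
        self.accesses = 0
        return self

    def __getitem__(self, key):
        if isinstance(key, slice):
            self.accesses += len(range(*key.indices(len(self))))
        else:
            self.accesses += 1
        return str.__getitem__(self, key)


def test_single_pass_bounded_character_touches():
    rng = random.Random(7)
    for _ in range(20):
        doc = CountingStr(random_document(rng))
        list(tokenize(doc, emit_comments=True))
        assert doc.accesses <= 3 * max(len(doc), 1)


def test_reference_automaton_agreement_on_random_documents():
    rng = random.Random(11)
    for _ in range(500):
        doc = random_document(rng)
        assert as_triples(tokenize(doc, True)) == reference_tokenize(doc, True), doc


def test_reference_automaton_agreement_on_corpus_fixture_documents():
    from nmrstar.fixtures import FixtureSpec, generate_entry, EDGE_FLAGS

    for seed in range(50):
        text, _ = generate_entry(
            FixtureSpec(seed=seed, edge_flags=frozenset(EDGE_FLAGS))
        )
        assert as_triples(tokenize(text, True)) == reference_tokenize(text, True)


_ALPHABET = "ab_; '\"#\n\t$.?" + "ld"  # structural chars heavily weighted


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet=_ALPHABET, max_size=120))
def test_reference_automaton_agreement_or_same_failure(doc):
    """On arbitrary text both lexers agree, or both reject the document."""
    try:
        produced = as_triples(tokenize(doc, True))
    except StarLexError:
        with pytest.raises(RefLexError):
            reference_tokenize(doc, True)
        return
    assert produced == reference_tokenize(doc, True)


def test_reconstructed_stream_retokenizes_identically(corpus):
    """Re-encoding every token with canonical delimiters is lex-idempotent."""
    for name, text, _ in corpus[:100]:
        tokens = list(tokenize(text, emit_comments=True))
        parts = []
        for token in tokens:
            if token.kind is TokenKind.DATA_HEADER:
                parts.append(f"data_{token.text}")
            elif token.kind is TokenKind.SAVE_BEGIN:
                parts.append(f"save_{token.text}")
            elif token.kind is TokenKind.SAVE_END:
                parts.append("save_")
            elif token.kind is TokenKind.LOOP_BEGIN:
                parts.append("loop_")
            elif token.kind is TokenKind.LOOP_END:
                parts.append("stop_")
            elif token.kind is TokenKind.TAG:
                parts.append(token.text)
            elif token.kind is TokenKind.COMMENT:
                parts.append(f"#{token.text}\n")
            else:
                parts.append(format_value(token.text))
        rebuilt = "\n".join(parts)
        again = [(t.kind, t.text) for t in tokenize(rebuilt, emit_comments=True)]
        assert again == [(t.kind, t.text) for t in tokens], name
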