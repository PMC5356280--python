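import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from nmrstar import fixtures, parse_text  # noqa: E402

#: Corpus scale shared by the structural test battery: large enough that the
#: documented tokenizer edge cases each occur hundreds of times, small enough
#: to generate and parse in seconds.
CORPUS_N = 1000
CORPUS_SEED = 20230


@pytest.fixture(scope="session")
def corpus():
    """The seeded fixture corpus as (name, text, manifest) triples."""
    return list(fixtures.iter_corpus(CORPUS_N, CORPUS_SEED))


@pytest.fixture(scope="session")
def parsed_corpus(corpus):
    """The corpus with each member's strict parse attached."""
    return [
        (name, text, manifest, parse_text(text))
        for name, text, manifest in corpus
    ]
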