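import pytest

from medread.lexical import TextStats
from medread.synthetic import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """30 short generated documents with exact ground-truth stats."""
    spec = CorpusSpec(n_documents=30, words_range=(116, 600), seed=42)
    return generate_corpus(spec)


def make_stats(rng) -> TextStats:
    """Random but internally consistent TextStats."""
    sentences = int(rng.integers(1, 60))
    words = sentences * int(rng.integers(3, 40))
    poly = int(rng.integers(0, words + 1))
    cx = int(rng.integers(0, poly + 1))
    # each word >=1 syllable; polysyllables contribute at least 3
    syllables = words + 2 * poly + int(rng.integers(0, words))
    return TextStats(words, sentences, syllables, poly, cx)
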