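"""Token-level counting primitives for readability scoring.

Every readability formula consumes the same five counts: words, sentences,
syllables, polysyllabic words (>=3 syllables) and Gunning-Fog "complex"
words. This module produces them deterministically, so every downstream
score is reproducible bit-for-bit.

Syllabification is dictionary-first: words found in the bundled lexicon
(``data/syllable_lexicon.tsv``) get their curated count; everything else
falls through to a pure vowel-group heuristic. Both modes are exposed
because neither is canonical for English.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from .errors import DegenerateText

__all__ = [
    "TextStats",
    "tokenize_words",
    "count_syllables",
    "heuristic_syllables",
    "is_complex_word",
    "compute_stats",
    "load_lexicon",
]

# Maximal letter-initial runs; internal apostrophes and hyphens are kept so
# that "don't", "T-cell" and "anti-PD-L1" are single tokens. Standalone
# numbers and punctuation are not words.
_WORD_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*(?:['’-][A-Za-z0-9]+)*")

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def tokenize_words(sentence: str) -> list[str]:
    """Split a sentence into word tokens.

    Tokens are maximal alphabetic runs with internal apostrophes and
    hyphens preserved. Numerals are excluded: the readability formulas are
    defined on words, and numbers have no syllabification.
    """
    return _WORD_RE.findall(sentence)


@lru_cache(maxsize=1)
def load_lexicon() -> dict[str, int]:
    """Load the bundled word -> syllable-count lexicon (lowercase keys)."""
    text = (
        resources.files("medread.data")
        .joinpath("syllable_lexicon.tsv")
        .read_text(encoding="utf-8")
    )
    lex: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        word, count = line.split("\t")
        lex[word] = int(count)
    return lex


def heuristic_syllables(word: str) -> int:
    """Count syllables without a dictionary.

    Pure rule set: silent "-ed"/"-es" endings are stripped first, then
    vowel groups (a e i o u y) are counted and a silent terminal "e" is
    subtracted (kept when it carries the syllable, as in consonant+"le").
    Hyphen parts are counted independently and summed. Minimum one
    syllable per part.
    """
    if not word:
        raise ValueError("cannot count syllables of an empty string")
    total = 0
    for part in re.split(r"-+", word.lower()):
        part = part.replace("'", "").replace("’", "")
        if not part:
            continue
        total += _heuristic_part(part)
    return max(total, 1)


def _heuristic_part(part: str) -> int:
    # silent past-tense "ed" (not after t/d, which adds a spoken syllable)
    if len(part) > 3 and part.endswith("ed") and part[-3] not in "td":
        part = part[:-2]
    # silent plural/3rd-person "es" (after sibilants the e is spoken)
    elif len(part) > 3 and part.endswith("es") and part[-3] not in "sxzhl":
        part = part[:-2]
    groups = _VOWEL_GROUP_RE.findall(part)
    n = len(groups)
    if (
        n > 1
        and part.endswith("e")
        and groups[-1] == "e"
        and not (len(part) >= 3 and part.endswith("le") and part[-3] not in "aeiouy")
    ):
        n -= 1
    return max(n, 1)


def count_syllables(word: str, *, mode: str = "dictionary") -> int:
    """Count syllables of one token.

    mode="dictionary" (default) consults the bundled lexicon and falls back
    to the heuristic for unknown words; mode="heuristic" never touches the
    lexicon. Hyphenated compounds sum over their parts.
    """
    if not word:
        raise ValueError("cannot count syllables of an empty string")
    if mode == "heuristic":
        return heuristic_syllables(word)
    if mode != "dictionary":
        raise ValueError(f"unknown syllable mode: {mode!r}")
    lex = load_lexicon()
    key = word.lower().replace("’", "'")
    if key in lex:
        return lex[key]
    if "-" in key:
        return sum(
            count_syllables(p, mode="dictionary") for p in key.split("-") if p
        )
    return heuristic_syllables(word)


_INFLECTIONS = ("es", "ed", "ing")


def is_complex_word(
    word: str,
    position_in_sentence: int = 1,
    *,
    syllable_mode: str = "dictionary",
) -> bool:
    """Gunning-Fog complex-word test.

    A word is complex when it has three or more syllables, except:

    * proper nouns — approximated as words capitalized anywhere but
      sentence-initially;
    * hyphenated compounds (classic Gunning guidance: familiar jargon and
      compounds are exempt);
    * words that reach three syllables only through the inflections
      "-es", "-ed", "-ing".
    """
    syl = count_syllables(word, mode=syllable_mode)
    if syl < 3:
        return False
    if position_in_sentence > 0 and word[:1].isupper():
        return False
    if "-" in word:
        return False
    lower = word.lower()
    for suffix in _INFLECTIONS:
        if lower.endswith(suffix) and len(lower) > len(suffix) + 1:
            base = lower[: -len(suffix)]
            # restore a dropped silent e: "creating" -> "create"
            for candidate in (base, base + "e"):
                if count_syllables(candidate, mode=syllable_mode) < 3:
                    return False
    return True


@dataclass(frozen=True)
class TextStats:
    """Aggregate counts for one document.

    Invariants: complex_word_count <= polysyllable_count <= word_count and
    syllable_count >= word_count (every word has at least one syllable).
    """

    word_count: int
    sentence_count: int
    syllable_count: int
    polysyllable_count: int
    complex_word_count: int

    @property
    def words_per_sentence(self) -> float:
        return self.word_count / self.sentence_count

    @property
    def syllables_per_word(self) -> float:
        return self.syllable_count / self.word_count

    def __add__(self, other: "TextStats") -> "TextStats":
        return TextStats(
            self.word_count + other.word_count,
            self.sentence_count + other.sentence_count,
            self.syllable_count + other.syllable_count,
            self.polysyllable_count + other.polysyllable_count,
            self.complex_word_count + other.complex_word_count,
        )


def compute_stats(
    sentences: Sequence[str] | Iterable[str],
    *,
    syllable_mode: str = "dictionary",
) -> TextStats:
    """Aggregate the counting primitives over a list of sentences.

    Raises DegenerateText when there are no sentences or no words, since
    every formula divides by both counts.
    """
    words = 0
    n_sentences = 0
    syllables = 0
    poly = 0
    complex_words = 0
    for sentence in sentences:
        tokens = tokenize_words(sentence)
        if not tokens and not sentence.strip():
            continue
        n_sentences += 1
        for pos, token in enumerate(tokens):
            syl = count_syllables(token, mode=syllable_mode)
            words += 1
            syllables += syl
            if syl >= 3:
                poly += 1
                if is_complex_word(token, pos, syllable_mode=syllable_mode):
                    complex_words += 1
    if n_sentences == 0 or words == 0:
        raise DegenerateText("no scoreable sentences or words")
    return TextStats(words, n_sentences, syllables, poly, complex_words)
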