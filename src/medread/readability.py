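"""The four readability formulas and the consensus school-level grade.

Scores
------
FRES  Flesch Reading Ease, 206.835 - 1.015*(words/sentence)
      - 84.6*(syllables/word). Higher is easier; nominal range 0-100 but
      the formula is unbounded on both sides and is reported raw.
FKGL  Flesch-Kincaid Grade Level, 0.39*(words/sentence)
      + 11.8*(syllables/word) - 15.59. A US school grade; may be negative
      for very simple text and is not clamped.
GFI   Gunning Fog Index, 0.4*[(words/sentence) + 100*(complex/words)].
SMOG  1.0430*sqrt(polysyllables * 30/sentences) + 3.1291. Defined on
      30-sentence samples; shorter texts are scored with the same
      normalization and a logged warning.

FRES is an ease score, not a grade, so averaging it with the other three
requires a conversion: the standard Flesch interpretation bands are mapped
to their midpoint school grades (configurable via ``fres_grade_map``).
The consensus grade is the arithmetic mean of the four per-formula grades,
classified into school bands: <=6 recommended, 7-8 middle school, 9-12
high school, 13-16 university, >=17 graduate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

from .lexical import TextStats
from .errors import DegenerateText

__all__ = [
    "ReadabilityResult",
    "compute_fres",
    "compute_fkgl",
    "compute_gfi",
    "compute_smog",
    "fres_to_grade",
    "consensus_grade",
    "classify_school_level",
    "score_stats",
    "DEFAULT_FRES_GRADE_MAP",
    "SCHOOL_BANDS",
]

log = logging.getLogger(__name__)

#: Flesch interpretation bands -> representative (midpoint) school grade.
#: (lower FRES bound inclusive, grade); scanned top-down.
DEFAULT_FRES_GRADE_MAP: tuple[tuple[float, float], ...] = (
    (90.0, 5.0),    # very easy: 5th grade
    (80.0, 6.0),    # easy
    (70.0, 7.0),    # fairly easy
    (60.0, 8.5),    # plain English: 8th-9th grade
    (50.0, 11.0),   # fairly difficult: 10th-12th
    (30.0, 14.5),   # difficult: college
    (-math.inf, 17.0),  # very difficult: college graduate
)

#: school-level bands on the consensus grade (name, lower, upper); bands are
#: half-open [lower, upper) except "recommended", closed at 6 to honor the
#: sixth-grade-or-below recommendation.
SCHOOL_BANDS: tuple[tuple[str, float, float], ...] = (
    ("recommended", -math.inf, 6.0),
    ("middle_school", 6.0, 9.0),
    ("high_school", 9.0, 13.0),
    ("university", 13.0, 17.0),
    ("graduate", 17.0, math.inf),
)

SCHOOL_LEVELS = tuple(name for name, _, _ in SCHOOL_BANDS)


def _check(stats: TextStats) -> None:
    if stats.word_count <= 0 or stats.sentence_count <= 0:
        raise DegenerateText("cannot score text with zero words or sentences")


def compute_fres(stats: TextStats) -> float:
    """Flesch Reading Ease Score (higher = easier)."""
    _check(stats)
    return (
        206.835
        - 1.015 * stats.words_per_sentence
        - 84.6 * stats.syllables_per_word
    )


def compute_fkgl(stats: TextStats) -> float:
    """Flesch-Kincaid Grade Level (may be negative; not clamped)."""
    _check(stats)
    return (
        0.39 * stats.words_per_sentence
        + 11.8 * stats.syllables_per_word
        - 15.59
    )


def compute_gfi(stats: TextStats) -> float:
    """Gunning Fog Index."""
    _check(stats)
    return 0.4 * (
        stats.words_per_sentence
        + 100.0 * stats.complex_word_count / stats.word_count
    )


def compute_smog(stats: TextStats) -> float:
    """SMOG grade, normalized to a 30-sentence sample.

    Texts under 30 sentences are outside the formula's validity domain;
    they are scored with the same normalization and a warning is logged.
    """
    _check(stats)
    if stats.sentence_count < 30:
        log.warning(
            "SMOG computed on %d sentences (<30, outside validity domain)",
            stats.sentence_count,
        )
    return 1.0430 * math.sqrt(
        stats.polysyllable_count * 30.0 / stats.sentence_count
    ) + 3.1291


def fres_to_grade(
    fres: float,
    grade_map: Sequence[tuple[float, float]] = DEFAULT_FRES_GRADE_MAP,
) -> float:
    """Map a Flesch ease score onto a representative school grade."""
    if not math.isfinite(fres):
        raise ValueError("FRES must be finite")
    for lower, grade in grade_map:
        if fres >= lower:
            return grade
    return grade_map[-1][1]


def consensus_grade(grades: Sequence[float]) -> float:
    """Arithmetic mean of the per-formula grade levels."""
    if not grades or not all(math.isfinite(g) for g in grades):
        raise ValueError("consensus requires finite grades")
    return sum(grades) / len(grades)


def classify_school_level(mean_grade: float) -> str:
    """Deterministically assign a consensus grade to a school band."""
    if not math.isfinite(mean_grade):
        raise ValueError("grade must be finite")
    if mean_grade <= 6.0:
        return "recommended"
    if mean_grade < 9.0:
        return "middle_school"
    if mean_grade < 13.0:
        return "high_school"
    if mean_grade < 17.0:
        return "university"
    return "graduate"


@dataclass(frozen=True)
class ReadabilityResult:
    """All four scores, their grade equivalents, and the consensus."""

    fres: float
    fkgl: float
    gfi: float
    smog: float
    fres_grade: float
    mean_grade: float
    school_level: str

    def to_dict(self) -> dict:
        return asdict(self)


def score_stats(
    stats: TextStats,
    grade_map: Sequence[tuple[float, float]] = DEFAULT_FRES_GRADE_MAP,
) -> ReadabilityResult:
    """Score one document's TextStats with all four formulas."""
    fres = compute_fres(stats)
    fkgl = compute_fkgl(stats)
    gfi = compute_gfi(stats)
    smog = compute_smog(stats)
    fres_grade = fres_to_grade(fres, grade_map)
    mean = consensus_grade((fres_grade, fkgl, gfi, smog))
    return ReadabilityResult(
        fres=fres,
        fkgl=fkgl,
        gfi=gfi,
        smog=smog,
        fres_grade=fres_grade,
        mean_grade=mean,
        school_level=classify_school_level(mean),
    )
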