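"""The four formulas, the grade conversion and the school-level bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medread.errors import DegenerateText
from medread.lexical import TextStats
from medread.readability import (
    classify_school_level,
    compute_fkgl,
    compute_fres,
    compute_gfi,
    compute_smog,
    consensus_grade,
    fres_to_grade,
    score_stats,
)
from tests.conftest import make_stats


def stats_from_ratios(wps=3.0, spw=1.0, complex_frac=0.0, poly=0,
                      sentences=10):
    words = int(round(wps * sentences))
    return TextStats(
        word_count=words,
        sentence_count=sentences,
        syllable_count=int(round(spw * words)),
        polysyllable_count=poly,
        complex_word_count=int(round(complex_frac * words)),
    )


def test_fres_direct_values():
    assert compute_fres(stats_from_ratios(3, 1)) == pytest.approx(119.190, abs=1e-9)
    s = TextStats(2143, 100, 3857, 0, 0)  # wps 21.43, spw ~1.7998
    expected = 206.835 - 1.015 * 21.43 - 84.6 * (3857 / 2143)
    assert compute_fres(s) == pytest.approx(expected, abs=1e-9)


def test_fkgl_direct_values():
    assert compute_fkgl(stats_from_ratios(3, 1)) == pytest.approx(-2.62, abs=1e-9)
    assert compute_fkgl(stats_from_ratios(20, 1.5)) == pytest.approx(9.91, abs=1e-9)
    # all-monosyllable single 100-word sentence: no cap applied
    s = TextStats(100, 1, 100, 0, 0)
    assert compute_fkgl(s) == pytest.approx(35.21, abs=1e-9)


def test_gfi_direct_values():
    assert compute_gfi(stats_from_ratios(3, 1, 0.0)) == pytest.approx(1.2, abs=1e-9)
    assert compute_gfi(stats_from_ratios(15, 1.2, 0.10)) == pytest.approx(10.0, abs=1e-9)
    s = TextStats(50, 5, 150, 50, 50)  # pathological: every word complex
    assert compute_gfi(s) == pytest.approx(0.4 * (10 + 100), abs=1e-9)


def test_smog_direct_values():
    assert compute_smog(TextStats(100, 10, 100, 0, 0)) == pytest.approx(3.1291, abs=1e-12)
    s = TextStats(600, 30, 900, 30, 30)
    assert compute_smog(s) == pytest.approx(1.0430 * math.sqrt(30) + 3.1291, abs=1e-9)
    # 30/sentences normalization: 10 polysyllables in 10 sentences scores the same
    s2 = TextStats(200, 10, 300, 10, 10)
    assert compute_smog(s2) == pytest.approx(1.0430 * math.sqrt(30) + 3.1291, abs=1e-9)


def test_degenerate_stats_raise():
    bad = TextStats(0, 1, 0, 0, 0)
    for fn in (compute_fres, compute_fkgl, compute_gfi, compute_smog):
        with pytest.raises(DegenerateText):
            fn(bad)


@pytest.mark.parametrize(
    ("fres", "grade"),
    [(95, 5), (85, 6), (75, 7), (65, 8.5), (51.72, 11), (40, 14.5),
     (9.15, 17), (90, 5), (30, 14.5), (29.999, 17), (-12.3, 17), (120, 5)],
)
def test_fres_to_grade_bands(fres, grade):
    assert fres_to_grade(fres) == grade


def test_consensus_grade():
    assert consensus_grade((10, 10, 10, 10)) == 10
    assert consensus_grade((11, 11.37, 14.53, 12.66)) == pytest.approx(12.39, abs=1e-9)
    assert consensus_grade((-2.62, 1.2, 3.1291, 5)) == pytest.approx(1.677275, abs=1e-9)


@pytest.mark.parametrize(
    ("grade", "band"),
    [(6.0, "recommended"), (-3.0, "recommended"), (6.01, "middle_school"),
     (8.99, "middle_school"), (9.0, "high_school"), (11.4, "high_school"),
     (12.999, "high_school"), (13.0, "university"), (16.999, "university"),
     (17.0, "graduate"), (40.0, "graduate")],
)
def test_classify_school_level(grade, band):
    assert classify_school_level(grade) == band


@settings(deadline=None, derandomize=True, max_examples=300)
@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_every_finite_grade_maps_to_exactly_one_band(grade):
    assert classify_school_level(grade) in {
        "recommended", "middle_school", "high_school", "university",
        "graduate",
    }


def test_monotonicity_in_syllables():
    lo = stats_from_ratios(20, 1.3, sentences=10)
    hi = TextStats(lo.word_count, lo.sentence_count, lo.syllable_count + 10,
                   lo.polysyllable_count, lo.complex_word_count)
    assert compute_fres(hi) < compute_fres(lo)
    assert compute_fkgl(hi) > compute_fkgl(lo)


def test_monotonicity_in_complex_and_poly():
    base = TextStats(200, 10, 300, 20, 10)
    more_cx = TextStats(200, 10, 300, 20, 15)
    more_poly = TextStats(200, 10, 300, 30, 10)
    assert compute_gfi(more_cx) > compute_gfi(base)
    assert compute_smog(more_poly) > compute_smog(base)


def test_smog_scale_invariance():
    a = TextStats(200, 10, 300, 12, 12)
    b = TextStats(600, 30, 900, 36, 36)
    assert compute_smog(a) == pytest.approx(compute_smog(b), abs=1e-12)


def test_smog_warns_below_thirty_sentences(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="medread.readability"):
        compute_smog(TextStats(50, 5, 80, 4, 4))
    assert any("validity" in rec.message for rec in caplog.records)


def test_score_stats_mean_is_exact_mean():
    rng = np.random.default_rng(11)
    for _ in range(50):
        stats = make_stats(rng)
        res = score_stats(stats)
        mean = (res.fres_grade + res.fkgl + res.gfi + res.smog) / 4
        assert res.mean_grade == pytest.approx(mean, abs=1e-9)
        assert res.school_level == classify_school_level(res.mean_grade)
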