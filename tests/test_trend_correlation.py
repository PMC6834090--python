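"""Annual aggregation, trial tallies and Pearson correlation."""

from datetime import date

import numpy as np
import pytest
from scipy import stats as sps

from medread.errors import DegenerateVariance, EmptySeries, MisalignedYears
from medread.synthetic import SeriesSpec, generate_correlated_series, write_series
from medread.trend_correlation import (
    AnnualSeries,
    MonthlySVI,
    TrialRecord,
    aggregate_annual_svi,
    pearson,
    read_trends_csv,
    read_trial_csv,
    trial_availability_by_year,
)


def monthly(values_by_year):
    months, vals = [], []
    for year, vs in sorted(values_by_year.items()):
        for m, v in enumerate(vs, start=1):
            months.append((year, m))
            vals.append(v)
    return MonthlySVI(tuple(months), tuple(vals))


def test_constant_year_mean():
    series = monthly({2010: [50.0] * 12})
    annual, coverage = aggregate_annual_svi(series, mode="mean")
    assert annual == AnnualSeries((2010,), (50.0,))
    assert coverage == {2010: 12}


def test_single_month_year_flagged_in_coverage():
    series = monthly({2010: [42.0]})
    annual, coverage = aggregate_annual_svi(series)
    assert annual.values == (42.0,)
    assert coverage[2010] == 1


def test_annual_means_match_bruteforce_loop():
    svi, _, _ = generate_correlated_series(SeriesSpec(seed=9))
    annual, _ = aggregate_annual_svi(svi, mode="mean")
    # independent per-year loop, no groupby machinery
    for year, value in zip(annual.years, annual.values):
        picked = [v for (y, _m), v in zip(svi.months, svi.values) if y == year]
        assert value == pytest.approx(sum(picked) / len(picked), abs=1e-12)


def test_empty_series_raises():
    with pytest.raises(EmptySeries):
        aggregate_annual_svi(MonthlySVI((), ()))


def records_from_years(years):
    return [
        TrialRecord(f"NCT{i:08d}", date(y, 6, 1)) for i, y in enumerate(years)
    ]


def test_trial_availability_cumulative_and_not():
    recs = records_from_years([2011])
    cum = trial_availability_by_year(recs, 2009, 2013, cumulative=True)
    assert cum.values == (0.0, 0.0, 1.0, 1.0, 1.0)
    inc = trial_availability_by_year(recs, 2009, 2013, cumulative=False)
    assert inc.values == (0.0, 0.0, 1.0, 0.0, 0.0)


def test_trial_tally_matches_bruteforce():
    rng = np.random.default_rng(4)
    years = rng.integers(2004, 2019, size=100)
    recs = records_from_years(list(years))
    inc = trial_availability_by_year(recs, 2004, 2018, cumulative=False)
    for year, value in zip(inc.years, inc.values):
        assert value == float(sum(1 for y in years if y == year))
    cum = trial_availability_by_year(recs, 2004, 2018, cumulative=True)
    assert list(cum.values) == list(np.cumsum(inc.values))
    assert all(b >= a for a, b in zip(cum.values, cum.values[1:]))


def test_filtered_records_not_counted():
    recs = [TrialRecord("A", date(2010, 1, 1), matches_filter=False)]
    out = trial_availability_by_year(recs, 2010, 2010, cumulative=False)
    assert out.values == (0.0,)


def years_series(values, start=2004):
    years = tuple(range(start, start + len(values)))
    return AnnualSeries(years, tuple(float(v) for v in values))


def test_pearson_exact_linear():
    x = years_series([1, 2, 3, 4, 5])
    assert pearson(x, years_series([3, 5, 7, 9, 11])).r == 1.0
    assert pearson(x, years_series([-1, -2, -3, -4, -5])).r == -1.0
    assert pearson(x, years_series([3, 5, 7, 9, 11])).p_two_sided == 0.0


def test_pearson_matches_t_transform():
    rng = np.random.default_rng(12)
    for _ in range(25):
        x = years_series(rng.normal(size=15))
        y = years_series(rng.normal(size=15))
        res = pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * sps.t.sf(abs(t), res.n - 2)
        assert res.p_two_sided == pytest.approx(p, abs=1e-9)
        assert -1 <= res.r <= 1 and 0 <= res.p_two_sided <= 1


def test_pearson_symmetry_and_affine_invariance():
    rng = np.random.default_rng(21)
    x = years_series(rng.normal(size=10))
    y = years_series(rng.normal(size=10))
    assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
    y2 = years_series(3.0 * np.asarray(y.values) + 7.0)
    assert pearson(x, y2).r == pytest.approx(pearson(x, y).r, abs=1e-12)


def test_pearson_p_decreases_with_abs_r():
    # same n, increasing |r| -> smaller p
    base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    noise = np.array([0.5, -1, 0.8, -0.2, 1.1, -0.7, 0.3, -0.9])
    p_prev = 1.1
    for scale in (3.0, 1.0, 0.3):
        y = years_series(base + scale * noise)
        res = pearson(years_series(base), y)
        assert res.p_two_sided < p_prev
        p_prev = res.p_two_sided


def test_pearson_errors():
    x = years_series([1, 2, 3])
    with pytest.raises(DegenerateVariance):
        pearson(x, years_series([5, 5, 5]))
    with pytest.raises(MisalignedYears):
        pearson(x, years_series([1, 2, 3], start=2005))
    with pytest.raises(ValueError):
        pearson(years_series([1, 2]), years_series([1, 2]))


def test_roundtrip_through_csv_files(tmp_path):
    spec = SeriesSpec(n_years=6, seed=3)
    paths = write_series(spec, tmp_path)
    svi = read_trends_csv(paths["trends"])
    recs = read_trial_csv(paths["trials"])
    direct_svi, direct_recs, _ = generate_correlated_series(spec)
    assert svi == direct_svi
    assert recs == direct_recs


def test_trends_csv_preamble_and_sub1(tmp_path):
    p = tmp_path / "trends.csv"
    p.write_text(
        "Category: All categories\n\n"
        "Month,cancer immunotherapy: (United States)\n"
        "2004-01,<1\n2004-02,7\n2004-03,8.5\n"
    )
    svi = read_trends_csv(p)
    assert svi.values == (0.5, 7.0, 8.5)
    assert svi.months[0] == (2004, 1)


def test_trial_csv_date_dialects(tmp_path):
    p = tmp_path / "trials.csv"
    p.write_text(
        "trial_id,first_posted\nA,2011-03-04\nB,\"March 5, 2012\"\n"
    )
    recs = read_trial_csv(p)
    assert [r.first_posted for r in recs] == [date(2011, 3, 4), date(2012, 3, 5)]
    dup = tmp_path / "dup.csv"
    dup.write_text("trial_id,first_posted\nA,2011-03-04\nA,2012-03-04\n")
    with pytest.raises(ValueError):
        read_trial_csv(dup)
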