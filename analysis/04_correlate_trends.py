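"""Correlate annual search interest with clinical-trial availability.

Reads the monthly SVI export and trial table from scratch/series/,
aggregates both to annual series (mean SVI; cumulative and incremental
trial counts), and writes Pearson r / p to results/correlation/.
"""

from pathlib import Path

from medread.trend_correlation import (
    aggregate_annual_svi,
    pearson,
    read_trends_csv,
    read_trial_csv,
    trial_availability_by_year,
    write_correlation,
)

ROOT = Path(__file__).resolve().parents[1]
SERIES = ROOT / "scratch" / "series"
OUT = ROOT / "results" / "correlation"


def main() -> None:
    svi = read_trends_csv(SERIES / "svi_monthly.csv")
    records = read_trial_csv(SERIES / "trials.csv")
    annual, coverage = aggregate_annual_svi(svi, mode="mean")
    short = {y: m for y, m in coverage.items() if m < 12}
    if short:
        print(f"warning: incomplete years {short}")

    for cumulative in (True, False):
        trials = trial_availability_by_year(
            records, annual.years[0], annual.years[-1], cumulative=cumulative)
        res = pearson(annual, trials)
        label = "cumulative" if cumulative else "incremental"
        print(f"{label:>12} trials: r = {res.r:.4f}, "
              f"p = {res.p_two_sided:.3g}, n = {res.n}")
        if cumulative:
            write_correlation(res, annual, trials, OUT,
                              flags={"svi_mode": "mean", "cumulative": True})
    print(f"wrote correlation.json and annual_series.csv -> {OUT}")


if __name__ == "__main__":
    main()
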