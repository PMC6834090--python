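"""Search-interest vs clinical-trial-availability correlation.

Inputs are a Google-Trends-style monthly search-volume-index (SVI) export
and a clinical-trial registry table with first-posted dates. Monthly SVI
is reduced to one value per calendar year (mean by default), trial
availability to a per-year series (cumulative count through each year by
default, since availability is a stock), and the two aligned annual
series are correlated with Pearson's r and a two-sided p-value from the
Student-t transform.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats as sps

from .errors import DegenerateVariance, EmptySeries, MisalignedYears

__all__ = [
    "MonthlySVI",
    "TrialRecord",
    "AnnualSeries",
    "CorrelationResult",
    "aggregate_annual_svi",
    "trial_availability_by_year",
    "pearson",
    "read_trends_csv",
    "read_trial_csv",
]


@dataclass(frozen=True)
class MonthlySVI:
    """Ordered (year, month, svi) triples; svi in [0, 100]."""

    months: tuple[tuple[int, int], ...]  # (year, month)
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.values):
            raise ValueError("months and values must align")
        if any(not 0.0 <= v <= 100.0 for v in self.values):
            raise ValueError("SVI values must lie in [0, 100]")
        if list(self.months) != sorted(set(self.months)):
            raise ValueError("months must be strictly increasing")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    first_posted: date
    matches_filter: bool = True


@dataclass(frozen=True)
class AnnualSeries:
    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must align")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p_two_sided": self.p_two_sided, "n": self.n}


def aggregate_annual_svi(
    series: MonthlySVI, mode: str = "mean"
) -> tuple[AnnualSeries, dict[int, int]]:
    """Reduce monthly SVI to one value per calendar year.

    Returns the annual series and a coverage report mapping each year to
    its month count (callers should warn when coverage < 12).
    """
    if not series.months:
        raise EmptySeries("no monthly observations")
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    by_year: dict[int, list[float]] = {}
    for (year, _month), value in zip(series.months, series.values):
        by_year.setdefault(year, []).append(value)
    years = tuple(sorted(by_year))
    agg = np.mean if mode == "mean" else np.sum
    values = tuple(float(agg(by_year[y])) for y in years)
    coverage = {y: len(by_year[y]) for y in years}
    return AnnualSeries(years, values), coverage


def trial_availability_by_year(
    records: Iterable[TrialRecord],
    start: int,
    end: int,
    cumulative: bool = True,
) -> AnnualSeries:
    """Per-year trial availability from first-posted dates.

    Counts records passing the filter whose first-posted date falls in
    each year of [start, end]. With ``cumulative`` (default) the series is
    the running total through each year — availability is a stock, not a
    flow. Years with no trials are reported as zero.
    """
    if start > end:
        raise ValueError("start year after end year")
    years = tuple(range(start, end + 1))
    counts = {y: 0 for y in years}
    for rec in records:
        if rec.matches_filter and start <= rec.first_posted.year <= end:
            counts[rec.first_posted.year] += 1
    values = [float(counts[y]) for y in years]
    if cumulative:
        values = list(np.cumsum(values))
    return AnnualSeries(years, tuple(float(v) for v in values))


def pearson(series_x: AnnualSeries, series_y: AnnualSeries) -> CorrelationResult:
    """Pearson product-moment correlation of two aligned annual series.

    The two-sided p-value comes from t = r*sqrt((n-2)/(1-r^2)) against
    Student's t with n-2 degrees of freedom (scipy's exact equivalent).
    """
    if series_x.years != series_y.years:
        raise MisalignedYears(
            f"year vectors differ: {series_x.years} vs {series_y.years}"
        )
    n = len(series_x.years)
    if n < 3:
        raise ValueError("need at least 3 paired years")
    x = np.asarray(series_x.values, dtype=float)
    y = np.asarray(series_y.values, dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateVariance("a constant series has no defined correlation")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    # exactly collinear inputs: snap to +/-1 instead of 1 - one ulp
    xc, yc = x - x.mean(), y - y.mean()
    slope = float(xc @ yc) / float(xc @ xc)
    if np.array_equal(yc, slope * xc):
        r = math.copysign(1.0, slope)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p_two_sided=p, n=n)


# --- file readers ----------------------------------------------------------

_MONTH_ROW_RE = re.compile(r"^(\d{4})-(\d{2}),\s*(\d+(?:\.\d+)?)\s*$")

_DATE_FORMATS = ("%Y-%m-%d", "%B %d, %Y", "%b %d, %Y")


def read_trends_csv(path: str | Path) -> MonthlySVI:
    """Parse a Google-Trends-style monthly CSV export.

    Tolerates the export preamble (category line and blank line) before
    the ``Month,...`` header; data rows are ``YYYY-MM,value``. Values like
    "<1" are read as 0.5.
    """
    months: list[tuple[int, int]] = []
    values: list[float] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.lower().startswith(("category", "month")):
            continue
        if line.startswith('"'):
            continue
        row = line.replace("<1", "0.5")
        m = _MONTH_ROW_RE.match(row)
        if m:
            months.append((int(m.group(1)), int(m.group(2))))
            values.append(float(m.group(3)))
    if not months:
        raise EmptySeries(f"{path}: no monthly rows found")
    return MonthlySVI(tuple(months), tuple(values))


def _parse_date(text: str) -> date:
    text = text.strip()
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {text!r}")


def read_trial_csv(path: str | Path) -> list[TrialRecord]:
    """Read a trial table CSV with columns trial_id, first_posted
    (ISO-8601 or "Month DD, YYYY") and optional matches_filter."""
    import csv

    records: list[TrialRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            tid = row["trial_id"].strip()
            if tid in seen:
                raise ValueError(f"{path}: duplicate trial_id {tid!r}")
            seen.add(tid)
            matches = str(row.get("matches_filter", "true")).strip().lower()
            records.append(
                TrialRecord(
                    trial_id=tid,
                    first_posted=_parse_date(row["first_posted"]),
                    matches_filter=matches in ("true", "1", "yes"),
                )
            )
    return records


def write_correlation(
    result: CorrelationResult,
    x: AnnualSeries,
    y: AnnualSeries,
    out_dir: str | Path,
    *,
    flags: dict | None = None,
) -> list[Path]:
    """Write the correlation JSON and the aligned annual table CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "correlation.json"
    payload = dict(result.to_dict())
    if flags:
        payload["flags"] = flags
    jpath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    cpath = out / "annual_series.csv"
    lines = ["year,svi,trials"]
    for yr, a, b in zip(x.years, x.values, y.values):
        lines.append(f"{yr},{a:.6g},{b:.6g}")
    cpath.write_text("\n".join(lines) + "\n")
    return [jpath, cpath]
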