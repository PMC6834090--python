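"""Corpus-level aggregation: summary statistics and the school-level
distribution.

``summarize`` reduces per-document (TextStats, ReadabilityResult) pairs to
the two standard result surfaces of a readability survey: a metric table
(mean, sample SD, min-max range for word count, words per sentence and
each formula) and the distribution of documents over school-level bands
with whole-percent shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientCorpus
from .lexical import TextStats
from .readability import ReadabilityResult, SCHOOL_LEVELS

__all__ = ["CorpusSummary", "summarize", "write_summary"]

#: reported metrics, in table order
METRICS = ("word_count", "words_per_sentence", "fres", "fkgl", "gfi", "smog")


@dataclass(frozen=True)
class CorpusSummary:
    """Mean/SD/range per metric plus the school-band distribution."""

    n_documents: int
    metrics: dict[str, dict[str, float]]  # metric -> {mean, sd, min, max}
    band_counts: dict[str, tuple[int, int]]  # band -> (count, percent)

    def metric_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.metrics).T.loc[list(METRICS)]
        return df[["mean", "sd", "min", "max"]]

    def band_frame(self) -> pd.DataFrame:
        rows = [
            {"school_level": b, "count": c, "percent": p}
            for b, (c, p) in self.band_counts.items()
        ]
        return pd.DataFrame(rows)


def _whole_percents(counts: Sequence[int], n: int) -> list[int]:
    """Whole-percent shares that sum to exactly 100.

    Largest-remainder apportionment: floor everything, then hand the
    leftover points to the largest fractional remainders (ties broken by
    band order). Plain independent rounding can sum to 99 or 101, which
    would break the distribution-table contract.
    """
    exact = [100.0 * c / n for c in counts]
    floors = [int(np.floor(e)) for e in exact]
    leftover = 100 - sum(floors)
    remainders = sorted(
        range(len(counts)), key=lambda i: (exact[i] - floors[i], -i),
        reverse=True,
    )
    out = list(floors)
    for i in remainders[:leftover]:
        out[i] += 1
    return out


def summarize(
    results: Sequence[tuple[TextStats, ReadabilityResult]],
) -> CorpusSummary:
    """Aggregate per-document results into a corpus summary.

    Sample (n-1) standard deviations; requires at least two documents.
    Permutation-invariant in the document order.
    """
    n = len(results)
    if n < 2:
        raise InsufficientCorpus(f"need >=2 documents, got {n}")

    values = {
        "word_count": [float(s.word_count) for s, _ in results],
        "words_per_sentence": [s.words_per_sentence for s, _ in results],
        "fres": [r.fres for _, r in results],
        "fkgl": [r.fkgl for _, r in results],
        "gfi": [r.gfi for _, r in results],
        "smog": [r.smog for _, r in results],
    }
    metrics = {}
    for name in METRICS:
        arr = np.asarray(values[name], dtype=float)
        metrics[name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    counts = [
        sum(1 for _, r in results if r.school_level == band)
        for band in SCHOOL_LEVELS
    ]
    pcts = _whole_percents(counts, n)
    band_counts = {
        band: (c, p) for band, c, p in zip(SCHOOL_LEVELS, counts, pcts)
    }

    return CorpusSummary(n_documents=n, metrics=metrics,
                         band_counts=band_counts)


def write_summary(summary: CorpusSummary, out_dir: str | Path) -> list[Path]:
    """Write the metric table (CSV), band distribution (CSV) and a JSON
    dump of the whole summary. Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    metric_csv = out / "corpus_summary.csv"
    df = summary.metric_frame().rename(
        columns={"mean": "Mean", "sd": "SD", "min": "Min", "max": "Max"}
    )
    df.index.name = "metric"
    df.to_csv(metric_csv, float_format="%.4f")
    paths.append(metric_csv)

    band_csv = out / "school_level_distribution.csv"
    summary.band_frame().to_csv(band_csv, index=False)
    paths.append(band_csv)

    json_path = out / "corpus_summary.json"
    payload = {
        "n_documents": summary.n_documents,
        "metrics": summary.metrics,
        "band_counts": {
            b: {"count": c, "percent": p}
            for b, (c, p) in summary.band_counts.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths.append(json_path)
    return paths
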