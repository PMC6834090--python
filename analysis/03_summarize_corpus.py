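"""Aggregate per-document scores into the corpus summary tables.

Reads results/readability/documents.json and writes the metric table
(mean / SD / range per metric) and the school-level distribution to
results/readability/. Prints both tables.
"""

import json
from pathlib import Path

from medread.corpus_report import summarize, write_summary
from medread.lexical import TextStats
from medread.readability import ReadabilityResult

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "readability"


def main() -> None:
    records = json.loads((OUT / "documents.json").read_text())
    results = []
    for rec in records:
        s = rec["stats"]
        stats = TextStats(s["word_count"], s["sentence_count"],
                          s["syllable_count"], s["polysyllable_count"],
                          s["complex_word_count"])
        results.append((stats, ReadabilityResult(**rec["scores"])))
    summary = summarize(results)
    write_summary(summary, OUT)
    print(f"n = {summary.n_documents} documents\n")
    print(summary.metric_frame().round(2).to_string())
    print()
    print(summary.band_frame().to_string(index=False))
    none_recommended = summary.band_counts["recommended"][0] == 0
    print("\nno document at the recommended sixth-grade level:"
          f" {none_recommended}")


if __name__ == "__main__":
    main()
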