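"""Score the simulated web corpus with all four readability formulas.

Extracts prose from each fixture in scratch/fixtures/, verifies the
extraction against the generator's recorded ground truth, scores every
document, and writes per-document records to results/readability/.
"""

import json
import logging
from pathlib import Path

from medread.html_text import FilterConfig, read_document
from medread.lexical import compute_stats
from medread.readability import score_stats

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
OUT = ROOT / "results" / "readability"


def main() -> None:
    logging.getLogger("medread.readability").setLevel(logging.ERROR)
    truth = json.loads((FIXTURES / "ground_truth.json").read_text())
    config = FilterConfig(min_words=50)
    records = []
    mismatches = 0
    for entry in truth["documents"]:
        doc = read_document(str(FIXTURES / entry["file"]), config)
        if doc.excluded:
            print(f"  excluded {entry['file']}: {doc.exclusion_reason}")
            continue
        stats = compute_stats(doc.sentences)
        if stats.word_count != entry["stats"]["word_count"]:
            mismatches += 1
        result = score_stats(stats)
        records.append({
            "file": entry["file"],
            "stats": {
                "word_count": stats.word_count,
                "sentence_count": stats.sentence_count,
                "syllable_count": stats.syllable_count,
                "polysyllable_count": stats.polysyllable_count,
                "complex_word_count": stats.complex_word_count,
                "words_per_sentence": stats.words_per_sentence,
            },
            "scores": result.to_dict(),
        })
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "documents.json").write_text(
        json.dumps(records, indent=2, sort_keys=True) + "\n")
    print(f"scored {len(records)} documents -> {OUT / 'documents.json'}")
    print(f"extraction word-count mismatches vs ground truth: {mismatches}")
    grades = [r["scores"]["mean_grade"] for r in records]
    print(f"consensus grades span {min(grades):.2f}-{max(grades):.2f}")


if __name__ == "__main__":
    main()
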