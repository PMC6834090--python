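"""Generate every input the downstream analyses consume.

Writes 50 HTML fixtures (heavy boilerplate) with a ground-truth sidecar to
scratch/fixtures/, and a 15-year monthly SVI export plus a clinical-trial
table to scratch/series/. Everything is seeded, so reruns are identical.
"""

import json
from pathlib import Path

from medread.synthetic import CorpusSpec, SeriesSpec, write_corpus, write_series

SEED = 2019  # study-period vintage of the emulated inputs
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"


def main() -> None:
    fixtures = SCRATCH / "fixtures"
    sidecar = write_corpus(CorpusSpec(seed=SEED), fixtures, "heavy")
    truth = json.loads(sidecar.read_text())
    n = len(truth["documents"])
    words = [d["stats"]["word_count"] for d in truth["documents"]]
    print(f"wrote {n} HTML fixtures to {fixtures}")
    print(f"  word counts span {min(words)}-{max(words)} "
          f"(ground truth recorded in {sidecar.name})")

    series_dir = SCRATCH / "series"
    paths = write_series(SeriesSpec(seed=SEED), series_dir)
    truth = json.loads(paths["truth"].read_text())
    print(f"wrote monthly SVI + trial CSVs to {series_dir}")
    print(f"  latent annual correlation this draw: "
          f"{truth['realized_latent_rho']:.4f} "
          f"(target {truth['spec']['target_rho']})")


if __name__ == "__main__":
    main()
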