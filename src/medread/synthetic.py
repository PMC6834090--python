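"""Synthetic inputs for the whole pipeline.

Live web pages, search-interest exports and registry extracts are
ephemeral, so every input the pipeline consumes can be generated here with
recorded ground truth:

* prose corpora with controlled words-per-sentence, syllables-per-word and
  complex-word structure, assembled from a syllable-stratified word bank
  (the bundled lexicon), so the generator knows the exact counts of what
  it emits;
* HTML fixtures wrapping a known body in navigation/boilerplate;
* paired monthly-SVI / trial-record series whose annual values share a
  latent bivariate-normal structure with a specified Pearson correlation.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path

import numpy as np

from .errors import InfeasibleSpec
from .html_text import ABBREVIATIONS
from .lexical import TextStats, load_lexicon
from .trend_correlation import MonthlySVI, TrialRecord

__all__ = [
    "CorpusSpec",
    "SeriesSpec",
    "word_bank",
    "generate_corpus",
    "wrap_html",
    "generate_correlated_series",
    "write_corpus",
    "write_series",
]

_ALPHA_RE = re.compile(r"^[a-z]{2,}$")

#: suffixes that make the Gunning-Fog complexity of a word depend on its
#: base form; excluded from the bank's complex stratum so ground truth is
#: unambiguous
_INFLECTION_SUFFIXES = ("es", "ed", "ing")


def word_bank() -> dict[int, list[str]]:
    """The lexicon stratified by syllable count.

    Strata 1-2 hold the filler vocabulary; strata >=3 hold only words
    whose Gunning-Fog complexity is unambiguous (no -es/-ed/-ing ending),
    so a generated document's complex-word count is exact by construction.
    Single-letter words and sentence-splitting abbreviations are excluded.
    """
    bank: dict[int, list[str]] = {}
    for word, syl in load_lexicon().items():
        if not _ALPHA_RE.match(word) or word in ABBREVIATIONS:
            continue
        if syl >= 3 and word.endswith(_INFLECTION_SUFFIXES):
            continue
        bank.setdefault(syl, []).append(word)
    for syl in bank:
        bank[syl].sort()
    return bank


@dataclass(frozen=True)
class CorpusSpec:
    """Targets for a generated prose corpus.

    Defaults emulate a survey of patient-facing cancer-immunotherapy web
    pages: mean sentence length ~21.4 words (SD ~4.9), ~1.58 syllables
    per word, ~15% complex words, document lengths log-uniform between
    116 and 5046 words.
    """

    n_documents: int = 50
    target_words_per_sentence: float = 21.43
    wps_jitter_sd: float = 4.86
    target_syllables_per_word: float = 1.58
    target_complex_fraction: float = 0.15
    words_range: tuple[int, int] = (116, 5046)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.words_range
        if not (50 <= lo <= hi <= 10000):
            raise InfeasibleSpec("words_range must lie within [50, 10000]")
        if self.target_words_per_sentence <= 0 or self.wps_jitter_sd < 0:
            raise InfeasibleSpec("sentence-length targets must be positive")
        if not 0.0 <= self.target_complex_fraction <= 1.0:
            raise InfeasibleSpec("complex fraction must lie in [0, 1]")
        if self.target_syllables_per_word < 1.0:
            raise InfeasibleSpec("syllables per word cannot be below 1")
        cf = self.target_complex_fraction
        # fillers span 1..2 syllables, complex words average ~3.5
        lo_spw = cf * 3.0 + (1 - cf) * 1.0
        hi_spw = cf * 6.0 + (1 - cf) * 2.0
        if not lo_spw - 1e-9 <= self.target_syllables_per_word <= hi_spw:
            raise InfeasibleSpec(
                "syllables-per-word target unreachable at this complex fraction"
            )


def _draw_complex(rng: np.random.Generator, bank: dict[int, list[str]]) -> tuple[str, int]:
    strata = [s for s in (3, 4, 5, 6) if bank.get(s)]
    weights = np.array([len(bank[s]) for s in strata], dtype=float)
    s = int(rng.choice(strata, p=weights / weights.sum()))
    return bank[s][int(rng.integers(len(bank[s])))], s


def generate_corpus(spec: CorpusSpec) -> list[tuple[TextStats, str]]:
    """Generate documents with exactly-known TextStats.

    Returns (ground-truth stats, prose) pairs. The stats are tallied from
    the emitted words' bank syllable counts, not recomputed by the
    counting module, so they are an independent oracle for it.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bank = word_bank()
    mean_cx_syl = 3.46  # stratum-size-weighted mean of complex-word syllables
    docs: list[tuple[TextStats, str]] = []
    lo, hi = spec.words_range
    for _ in range(spec.n_documents):
        n_words = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        n_words = min(max(n_words, lo), hi)
        sentences: list[str] = []
        words = syllables = poly = cx = 0
        while words < n_words:
            length = int(round(rng.normal(spec.target_words_per_sentence,
                                          spec.wps_jitter_sd)))
            length = max(3, min(length, 60, n_words - words))
            if n_words - words - length < 3:
                length = n_words - words
            n_cx = int(rng.binomial(length, spec.target_complex_fraction))
            n_cx = min(n_cx, length)
            picked: list[tuple[str, int]] = []
            cx_syl = 0
            for _i in range(n_cx):
                w, s = _draw_complex(rng, bank)
                picked.append((w, s))
                cx_syl += s
            n_fill = length - n_cx
            if n_fill > 0:
                want = spec.target_syllables_per_word * length - cx_syl
                p2 = (want - n_fill) / n_fill  # P(filler has 2 syllables)
                p2 = min(max(p2, 0.0), 1.0)
                for _i in range(n_fill):
                    s = 2 if rng.random() < p2 else 1
                    stratum = bank[s]
                    picked.append((stratum[int(rng.integers(len(stratum)))], s))
            order = rng.permutation(len(picked))
            toks = [picked[i] for i in order]
            text = " ".join(w for w, _ in toks)
            text = text[0].upper() + text[1:] + "."
            sentences.append(text)
            words += len(toks)
            syllables += sum(s for _, s in toks)
            n_poly = sum(1 for _, s in toks if s >= 3)
            poly += n_poly
            cx += n_poly  # complex stratum words are complex at any position
        stats = TextStats(words, len(sentences), syllables, poly, cx)
        docs.append((stats, " ".join(sentences)))
    return docs


# --- HTML fixtures ---------------------------------------------------------

_NAV_WORDS = ("Home", "About", "Contact", "News", "Events", "Donate",
              "Careers", "Privacy", "Terms", "Sitemap", "Login", "Search")


def _nav_links(rng: np.random.Generator, n: int) -> str:
    items = rng.choice(_NAV_WORDS, size=n, replace=True)
    return "".join(f'<li><a href="/{w.lower()}">{w}</a></li>' for w in items)


def wrap_html(
    prose: str,
    boilerplate_level: str = "light",
    seed: int = 0,
) -> tuple[str, str]:
    """Wrap prose in an HTML5 page with seeded boilerplate.

    Levels: "none" (bare body), "light" (nav/header/footer + a script),
    "heavy" (adds asides, link-farm divs inside the content and more
    chrome). Returns (html, ground-truth body prose). The body text always
    equals the input prose verbatim.
    """
    if not prose:
        raise ValueError("prose must be non-empty")
    if boilerplate_level not in ("none", "light", "heavy"):
        raise ValueError(f"unknown boilerplate level: {boilerplate_level!r}")
    rng = np.random.default_rng(seed)
    paragraphs = _split_paragraphs(prose, rng)
    body_core = "\n".join(f"<p>{p}</p>" for p in paragraphs)
    if boilerplate_level == "none":
        html = (
            "<!DOCTYPE html>\n<html><head><title>Patient information"
            f"</title></head>\n<body>\n{body_core}\n</body></html>\n"
        )
        return html, prose

    chrome_top = (
        f"<header><h1>Cancer Center</h1><nav><ul>{_nav_links(rng, 8)}"
        "</ul></nav></header>\n"
        "<script>var tracker = {'page': 'info', 'hits': 12};</script>\n"
    )
    chrome_bottom = (
        f"<footer><ul>{_nav_links(rng, 6)}</ul>"
        "<p>&copy; Example Health Network</p></footer>\n"
    )
    inner = body_core
    if boilerplate_level == "heavy":
        farm = (
            f'<div class="related"><ul>{_nav_links(rng, 12)}</ul></div>'
        )
        aside = (
            "<aside><h3>Related articles</h3>"
            f"<ul>{_nav_links(rng, 10)}</ul></aside>"
        )
        mid = len(paragraphs) // 2
        inner = "\n".join(
            [f"<p>{p}</p>" for p in paragraphs[:mid]]
            + [farm, aside]
            + [f"<p>{p}</p>" for p in paragraphs[mid:]]
        )
        chrome_top += "<style>body {font-family: serif;}</style>\n"
    html = (
        "<!DOCTYPE html>\n<html><head><title>Patient information</title>"
        "</head>\n<body>\n"
        f"{chrome_top}<main>\n{inner}\n</main>\n{chrome_bottom}"
        "</body></html>\n"
    )
    return html, prose


def _split_paragraphs(prose: str, rng: np.random.Generator) -> list[str]:
    # group sentences into 2-4 sentence paragraphs on sentence boundaries
    parts = re.split(r"(?<=[.!?]) ", prose)
    paragraphs: list[str] = []
    i = 0
    while i < len(parts):
        k = int(rng.integers(2, 5))
        paragraphs.append(" ".join(parts[i:i + k]))
        i += k
    return [p for p in paragraphs if p]


# --- correlated SVI / trial series ----------------------------------------

@dataclass(frozen=True)
class SeriesSpec:
    """Targets for a paired annual SVI / trial-count series.

    ``target_rho`` is the Pearson correlation of the latent annual pair.
    ``trend_share`` is the fraction of latent variance carried by a linear
    trend common to both margins (both real series rise over time); the
    residual correlation is solved so the total correlation equals
    ``target_rho``. ``trial_growth`` scales the trial-count dispersion.
    """

    n_years: int = 15
    start_year: int = 2004
    target_rho: float = 0.97
    svi_scale: float = 100.0
    trial_growth: float = 60.0
    trend_share: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 3:
            raise InfeasibleSpec("need at least 3 years")
        if not -1.0 < self.target_rho < 1.0:
            raise InfeasibleSpec("target_rho must lie in (-1, 1)")
        if not 0.0 < self.svi_scale <= 100.0:
            raise InfeasibleSpec("svi_scale must lie in (0, 100]")
        if self.trial_growth < 0:
            raise InfeasibleSpec("trial_growth must be non-negative")
        if not 0.0 <= self.trend_share < 1.0:
            raise InfeasibleSpec("trend_share must lie in [0, 1)")
        resid = (self.target_rho - self.trend_share) / (1.0 - self.trend_share)
        if not -1.0 <= resid <= 1.0:
            raise InfeasibleSpec(
                "trend_share incompatible with target_rho"
            )


def generate_correlated_series(
    spec: SeriesSpec,
) -> tuple[MonthlySVI, list[TrialRecord], float]:
    """Generate a monthly SVI series and trial records with correlated
    annual structure.

    Returns (monthly SVI, trial records, realized Pearson r of the latent
    annual pair). The SVI margin becomes monthly values (annual level +
    zero-mean seasonality + noise) rescaled so the series maximum equals
    ``svi_scale``; the trial margin becomes a per-year count of records
    via a rounded increasing affine transform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_years
    years = np.arange(spec.start_year, spec.start_year + n)

    trend = (years - years.mean()) / years.std(ddof=1)
    a2 = spec.trend_share
    rho_resid = (spec.target_rho - a2) / (1.0 - a2)
    e1 = rng.standard_normal(n)
    e2 = rho_resid * e1 + math.sqrt(1.0 - rho_resid**2) * rng.standard_normal(n)
    x = math.sqrt(a2) * trend + math.sqrt(1.0 - a2) * e1
    y = math.sqrt(a2) * trend + math.sqrt(1.0 - a2) * e2
    realized = float(np.corrcoef(x, y)[0, 1])

    # monthly SVI: annual level + seasonality + noise, max rescaled
    annual_level = np.clip(55.0 + 13.0 * x, 5.0, 98.0)
    months: list[tuple[int, int]] = []
    raw: list[float] = []
    for i, year in enumerate(years):
        for m in range(1, 13):
            season = 1.5 * math.sin(2.0 * math.pi * (m - 1) / 12.0)
            val = annual_level[i] + season + rng.normal(0.0, 0.7)
            months.append((int(year), m))
            raw.append(max(val, 0.5))
    arr = np.asarray(raw)
    arr = arr * (spec.svi_scale / arr.max())
    values = np.round(arr, 1)
    values[int(np.argmax(arr))] = spec.svi_scale  # Trends contract: max pins
    svi = MonthlySVI(tuple(months), tuple(float(v) for v in values))

    # trial records: per-year new trials from a rounded affine transform
    counts = np.maximum(0, np.round(150.0 + spec.trial_growth * y)).astype(int)
    records: list[TrialRecord] = []
    k = 0
    for i, year in enumerate(years):
        for j in range(counts[i]):
            month = 1 + (j * 12) // max(counts[i], 1)
            records.append(
                TrialRecord(
                    trial_id=f"NCT{90000000 + k:08d}",
                    first_posted=date(int(year), min(month, 12), 15),
                )
            )
            k += 1
    return svi, records, realized


# --- file writers ----------------------------------------------------------

def write_corpus(
    spec: CorpusSpec,
    out_dir: str | Path,
    boilerplate_level: str = "light",
) -> Path:
    """Write HTML fixture files plus a ground-truth JSON sidecar.

    Returns the sidecar path. Fixture ``doc_NNN.html`` wraps document
    NNN's prose; the sidecar records each document's exact TextStats.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs = generate_corpus(spec)
    truth = []
    for i, (stats, prose) in enumerate(docs):
        html, _body = wrap_html(prose, boilerplate_level, seed=spec.seed + i)
        name = f"doc_{i:03d}.html"
        (out / name).write_text(html, encoding="utf-8")
        truth.append({"file": name, "stats": asdict(stats), "body": prose})
    sidecar = out / "ground_truth.json"
    sidecar.write_text(json.dumps(
        {"spec": asdict(spec), "documents": truth}, indent=2) + "\n")
    return sidecar


def write_series(spec: SeriesSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a Trends-dialect SVI CSV, a trial CSV and a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    svi, records, realized = generate_correlated_series(spec)

    trends = out / "svi_monthly.csv"
    lines = ["Category: All categories", "",
             "Month,cancer immunotherapy: (United States)"]
    for (year, month), value in zip(svi.months, svi.values):
        v = int(value) if float(value).is_integer() else value
        lines.append(f"{year}-{month:02d},{v}")
    trends.write_text("\n".join(lines) + "\n")

    trials = out / "trials.csv"
    rows = ["trial_id,first_posted"]
    for rec in records:
        rows.append(f"{rec.trial_id},{rec.first_posted.isoformat()}")
    trials.write_text("\n".join(rows) + "\n")

    sidecar = out / "series_truth.json"
    sidecar.write_text(json.dumps(
        {"spec": asdict(spec), "realized_latent_rho": realized}, indent=2)
        + "\n")
    return {"trends": trends, "trials": trials, "truth": sidecar}
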