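# Methods

## Pipeline model

A web resource is modeled as `raw HTML → prose → sentences → counts →
scores → consensus grade → school band`. Each arrow is a deterministic
function, so two runs on the same bytes produce identical output; there is
no randomness anywhere in the measurement path.

### HTML → prose

Visible body text is taken from an HTML5-tolerant parse (lxml), after
removing `<script>`, `<style>`, `<noscript>`, `<template>`, `<nav>`,
`<header>`, `<footer>` and `<aside>` elements, and any block-level element
(`div`, `ul`, `ol`, `table`, `section`, `menu`, `p`) whose text is more
than 80% anchor text. The 80% anchor-density rule is the single
reproducibility-relevant extraction choice: it is what separates
navigation menus and link farms from paragraphs that merely contain a few
links. Input bytes are decoded as UTF-8 with undecodable bytes replaced.

Two page-level filters approximate the editorial inclusion judgment of a
human reviewer and *flag* rather than drop: a case-insensitive keyword
match in the title/headings for researcher-directed content (defaults:
"abstract", "doi", "conference", "workshop") and a minimum word count
(default 50) for "original content". Pages whose visible text is empty
but whose markup still contains anchor text are flagged as link-only;
pages with no visible text at all are a hard error.

### Sentence segmentation

A regex segmenter splits at runs of `.!?` followed by whitespace, with a
fixed, documented abbreviation list (Dr., e.g., U.S., month names, etc.),
protection for single-letter initials and dotted acronyms, and implicit
decimal protection (no whitespace inside "3.5"). Unknown abbreviations
cause over-splitting; that is accepted and surfaces as a shorter mean
sentence length rather than a crash. The segmentation is a partition:
joining the sentences and collapsing whitespace reproduces the prose.

### Counting

Word tokens are maximal letter-initial runs with internal apostrophes and
hyphens kept ("don't", "T-cell", "anti-PD-L1" are one token each);
standalone numerals are not words, since the formulas are defined on words
and numbers have no syllabification.

Syllables are dictionary-first: the bundled lexicon
(`data/syllable_lexicon.tsv`, ~3.2k entries of common and health-domain
vocabulary with curated counts, built from a hand-verified base list plus
regular morphological derivations) is consulted before a pure heuristic.
The heuristic counts vowel groups (a e i o u y), first stripping silent
`-ed` (except after t/d) and silent `-es` (except after sibilants and l),
then subtracting a silent terminal "e" unless it is the only vowel group
or follows consonant+l ("table"). Hyphen parts are counted independently
and summed; minimum one syllable per part. On the lexicon itself the
heuristic agrees with the curated counts on ~90.5% of entries — the
measured cost of running without the dictionary. Both modes are exposed
(`mode="dictionary" | "heuristic"`) because published readability studies
rarely state which they used.

A word is *complex* (for GFI) when it has ≥3 syllables and is not (a)
capitalized past the first sentence position (proper-noun approximation),
(b) a hyphenated compound, or (c) ≥3 syllables only through `-es`,
`-ed`, `-ing` — the inflection check strips the suffix, restores a
dropped silent e, and tests the base's syllable count.

### Scores and bands

The four formulas are evaluated exactly as printed in the README; no
flooring or capping is applied anywhere (FKGL may be negative on trivial
text, FRES can exceed 100 — both are legal, reported raw, and the corpus
minima/maxima stay meaningful). SMOG is defined on 30-sentence samples;
shorter documents are scored with the same `30/S` normalization and a
logged warning rather than refused, because short patient pages are
common and a missing score would bias a corpus summary.

FRES is converted to a grade by band midpoints (table in the README,
configurable via `fres_grade_map`) before averaging. This conversion is a
documented modeling choice, not a recovered convention: averaging an ease
score with grade-scaled formulas requires one, and any reasonable mapping
shifts the consensus by at most a grade within a band. The school-level
cut points follow the US convention — middle school 7–8, high school
9–12, university 13–16, graduate 17+ — half-open on the upper side, with
6 inclusive in "recommended" to honor "sixth grade or below".

### Corpus aggregation

Summary tables report mean, *sample* (n−1) SD and min–max per metric;
sample SD because a scored corpus is a sample of the resources a patient
might reach, not the population. Band percentages use largest-remainder
apportionment to whole percent, so they always sum to exactly 100
(independent rounding can sum to 99 or 101, which breaks the
distribution-table contract); ties in the remainders break by band order.

## Trend correlation

Monthly SVI reduces to annual values by mean (default) or sum; a coverage
report flags years with fewer than 12 months. Trial availability is the
count of registry records by first-posted year, by default accumulated
through each year — availability is a stock of open options, not a flow —
with `--incremental` exposing the per-year alternative; neither mode is
privileged in the API since published analyses often leave this
ambiguous. Pearson's r comes from `scipy.stats.pearsonr`; the two-sided
p-value from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. Exactly
collinear inputs are snapped to r = ±1 (detected by exact-zero residuals
of the least-squares fit, not a tolerance) so that perfectly linear series
do not report 1 − 1 ulp. Constant series raise a typed error rather than
returning NaN.

## Synthetic data

The generator emulates the *statistical shape* of a readability survey of
patient-facing cancer-immunotherapy pages, not its language. Documents
are assembled from the lexicon stratified by syllable count; sentence
lengths are Gaussian around the target words-per-sentence, filler words
mix 1- and 2-syllable entries to hit the syllables-per-word target, and
complex words are drawn binomially from the ≥3-syllable strata (excluding
`-es/-ed/-ing` forms so complexity is unambiguous). The generator tallies
exactly what it emits, so every fixture carries independent ground-truth
counts against which the counting module is tested. Defaults: 50
documents, words per sentence 21.43 (SD 4.86), 1.58 syllables per word,
15% complex words, document lengths log-uniform on 116–5046 words —
the observed ranges of such surveys. HTML wrapping adds seeded
navigation/footer/script boilerplate at three levels (`none`, `light`,
`heavy`), with body text verbatim.

What generated corpora do *not* emulate: real syntax and discourse,
encoding glitches, JavaScript-rendered content, and pages whose main text
is interleaved with captions and ads. Passing round-trip tests therefore
demonstrates that extraction and counting are exact on well-formed pages
with heavy but conventional boilerplate — not that any real page is
parsed perfectly.

The paired SVI/trial series draws one latent bivariate-normal value per
year at a target correlation ρ (default 0.97, n = 15 years from 2004). A
standardized linear trend common to both margins carries a configurable
share of the latent variance (default 0.5) — both real series rise over
time — and the residual correlation is solved so the *total* latent
correlation equals ρ. Margins map near-affinely to observables: annual
SVI level 55 + 13x clipped to [5, 98], expanded to months with zero-mean
seasonality (amplitude 1.5) and noise (SD 0.7), rescaled so the series
maximum is exactly 100 (the Trends normalization contract) and rounded to
one decimal; trial counts round(150 + 60y) floored at 0, emitted as
dated records spread through each year. Monte-Carlo calibration (1000
seeds) puts the mean recovered annual r at 0.970 for ρ = 0.97 and the
mean |r| at 0.21 under independence — the rounding and seasonal noise are
small enough that the observable series inherit the latent correlation.

## Problem sizes

The test suite and the acceptance script use corpora of 30–100 documents
of 116–800 words (the full 116–5046 range is exercised in the analysis
drivers), 200 random count vectors for the formula oracle, 10,000 grades
for classification totality, and 1000 seeds for the correlation sampling
distribution; the whole suite runs in well under a minute.

## Known limitations

- The proper-noun exemption is positional capitalization only; sentence-
  initial proper nouns are counted complex, and all-caps jargon is not
  exempted.
- The syllable heuristic has no hiatus handling ("create", "biology"
  undercount without the dictionary); the bundled lexicon covers the
  generator's vocabulary but not open English.
- The researcher-directed filter is a keyword approximation of an
  editorial judgment and is surfaced as a flag for exactly that reason.
- Pearson's r on two trending series measures co-movement, not causation;
  the cumulative mode in particular correlates two near-monotone series.
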