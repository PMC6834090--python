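"""HTML -> prose extraction and sentence segmentation.

Patient-facing web pages bury their prose in navigation menus, footers and
script blocks. Extraction keeps the visible body text and drops:

* ``<script>``, ``<style>``, ``<noscript>``, ``<template>`` content;
* structural boilerplate elements: ``<nav>``, ``<header>``, ``<footer>``,
  ``<aside>``;
* block elements whose text is more than 80% anchor text (link farms,
  menus marked up as plain lists).

Pages can also be *excluded* from a corpus without crashing: a
:class:`FilterConfig` flags researcher-directed pages (keyword match in the
title or headings) and pages with too little original content (word count
below a threshold, e.g. link-only pages). Exclusion is a flag on the
returned :class:`Document` because the editorial judgment it approximates
cannot be fully automated; callers decide whether to drop flagged pages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import lxml.html

from .errors import EmptyDocument
from .lexical import tokenize_words

__all__ = [
    "Document",
    "FilterConfig",
    "extract_prose",
    "split_sentences",
    "read_document",
]

#: default keywords flagging researcher-directed content
DEFAULT_EXCLUDE_PATTERNS = ("abstract", "doi", "conference", "workshop")

#: elements whose text is never prose
_DROP_TAGS = ("script", "style", "noscript", "template", "nav", "header",
              "footer", "aside")

#: block-level elements tested for the anchor-text-density rule
_BLOCK_TAGS = {"div", "ul", "ol", "table", "section", "menu", "p"}

#: a block more than this fraction anchor text is treated as navigation
_ANCHOR_DENSITY_LIMIT = 0.8


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion rules for corpus membership."""

    exclude_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS
    min_words: int = 50

    def __post_init__(self) -> None:
        if self.min_words < 1:
            raise ValueError("min_words must be >= 1")


@dataclass
class Document:
    """One web resource: identifier, raw HTML, extracted prose, sentences."""

    source_id: str
    prose: str
    raw_html: str | None = None
    sentences: list[str] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None


def _collapse_ws(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def _anchor_density(el: lxml.html.HtmlElement) -> float:
    total = _collapse_ws(el.text_content())
    if not total:
        return 0.0
    anchor = sum(len(_collapse_ws(a.text_content())) for a in el.iter("a"))
    return min(anchor / len(total), 1.0)


def extract_prose(
    raw_html: str,
    config: FilterConfig | None = None,
    *,
    source_id: str = "<string>",
) -> Document:
    """Extract visible prose from an HTML document.

    Raises :class:`EmptyDocument` when nothing visible survives. Filter
    hits set ``Document.excluded`` instead of raising, so pipelines can
    log the rule that fired and move on.
    """
    config = config or FilterConfig()
    root = lxml.html.document_fromstring(raw_html)

    title_parts = [root.findtext(".//title") or ""]
    for h in root.iter("h1", "h2", "h3"):
        title_parts.append(h.text_content())
    headline = " ".join(_collapse_ws(t) for t in title_parts).lower()

    for tag in _DROP_TAGS:
        for el in root.iter(tag):
            el.drop_tree()
    # drop link-dominated blocks; skip elements already inside a dropped one
    for el in list(root.iter()):
        if el.tag not in _BLOCK_TAGS:
            continue
        if el.getparent() is None or root not in el.iterancestors():
            continue
        if _anchor_density(el) > _ANCHOR_DENSITY_LIMIT:
            el.drop_tree()

    body = root.find("body")
    target = body if body is not None else root
    prose = _collapse_ws(target.text_content())

    doc = Document(source_id=source_id, prose=prose, raw_html=raw_html)
    if not prose:
        # a page that was only navigation is "no original content", an
        # exclusion; a page with no visible text at all is a hard error
        fresh = lxml.html.document_fromstring(raw_html)
        for tag in ("script", "style", "noscript", "template"):
            for el in fresh.iter(tag):
                el.drop_tree()
        bare = _collapse_ws(fresh.text_content())
        if bare:
            doc.excluded = True
            doc.exclusion_reason = "no original content (only hyperlinks)"
            return doc
        raise EmptyDocument(f"{source_id}: no visible text")

    for pattern in config.exclude_patterns:
        if pattern.lower() in headline:
            doc.excluded = True
            doc.exclusion_reason = f"researcher-directed keyword: {pattern!r}"
            return doc
    if len(tokenize_words(prose)) < config.min_words:
        doc.excluded = True
        doc.exclusion_reason = (
            f"below min_words={config.min_words} (original-content rule)"
        )
    return doc


# --- sentence segmentation -------------------------------------------------

#: abbreviations that never end a sentence (lowercase, no trailing dot)
ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "rev", "hon", "st", "jr", "sr",
    "vs", "etc", "e.g", "i.e", "cf", "al", "fig", "no", "vol", "approx",
    "dept", "univ", "inc", "ltd", "co", "corp", "jan", "feb", "mar",
    "apr", "jun", "jul", "aug", "sep", "sept", "oct", "nov", "dec",
})

_BOUNDARY_RE = re.compile(r"[.!?]+")


def _is_abbreviation(prefix: str) -> bool:
    """Does the text before a period end in a known abbreviation?"""
    m = re.search(r"(\S+)$", prefix)
    if not m:
        return False
    token = m.group(1).lstrip("(\"'“").lower()
    if token in ABBREVIATIONS:
        return True
    # single initials ("J.") and dotted acronyms ("U.S.")
    if re.fullmatch(r"(?:[a-z]\.)*[a-z]", token):
        return True
    return False


def split_sentences(prose: str) -> list[str]:
    """Split plain text into sentences.

    Boundaries are runs of terminal punctuation (. ! ?) followed by
    whitespace (or end of text), with protection for a fixed abbreviation
    list, single-letter initials and decimal numbers. The sentences
    partition the input: joining them with single spaces reproduces the
    whitespace-collapsed prose.
    """
    if not prose.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(prose):
        end = m.end()
        if end < len(prose) and not prose[end].isspace():
            continue  # mid-token punctuation, e.g. "3.5" has no space after
        if m.group().startswith("."):
            before = prose[start:m.start()]
            if _is_abbreviation(before):
                continue
        chunk = prose[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = prose[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def read_document(
    path: str,
    config: FilterConfig | None = None,
) -> Document:
    """Read an .html or .txt file into a segmented Document.

    Files are decoded as UTF-8; undecodable bytes are replaced (and the
    replacement count is recorded in the exclusion log by the CLI). A
    ``.txt`` file is treated as prose directly.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    text = raw.decode("utf-8", errors="replace")
    if path.lower().endswith((".htm", ".html")):
        doc = extract_prose(text, config, source_id=path)
    else:
        doc = Document(source_id=path, prose=_collapse_ws(text))
        config = config or FilterConfig()
        if len(tokenize_words(doc.prose)) < config.min_words:
            doc.excluded = True
            doc.exclusion_reason = f"below min_words={config.min_words}"
    doc.sentences = split_sentences(doc.prose)
    return doc
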