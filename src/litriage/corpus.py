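"""Abstract corpora: readers, offset-preserving tokenization and corpus statistics.

Documents are MEDLINE-style abstract records (PMID, title, abstract, year).
Tokenization is the single normalization contract shared by the vocabulary
index and the named-entity matcher: NFKC compatibility normalization plus
case folding, with alphanumeric runs as tokens and all punctuation
(including hyphens and en-dashes) acting as separators.  Character offsets
always index into the *original* section text so matched concepts can be
highlighted in context.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from lxml import etree

TITLE = "title"
ABSTRACT = "abstract"
SECTIONS = (TITLE, ABSTRACT)

YEAR_MIN, YEAR_MAX = 1800, 2100


@dataclass
class Document:
    """One abstract record."""

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    journal: str | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.year is not None and not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"pmid {self.pmid}: year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")

    def section_text(self, section: str) -> str:
        if section == TITLE:
            return self.title
        if section == ABSTRACT:
            return self.abstract
        raise ValueError(f"unknown section {section!r}")


@dataclass(frozen=True)
class Token:
    """A normalized token with offsets into the original section text."""

    surface: str
    start: int
    end: int
    section: str = ABSTRACT


@dataclass
class CorpusStats:
    """Corpus-level counts consumed by the BM25 and TF-IDF scorers."""

    n_docs: int
    avgdl: float
    df: dict[str, int] = field(default_factory=dict)
    concept_df: dict[str, int] = field(default_factory=dict)


def normalize_text(text: str) -> str:
    """NFKC + casefold, the same transform applied token-wise by the tokenizer."""
    return unicodedata.normalize("NFKC", text).casefold()


def normalize_tokens(text: str, section: str = ABSTRACT) -> list[Token]:
    """Tokenize ``text`` into normalized alphanumeric runs.

    Offsets are 0-based, half-open, into the original string.  Greek letters
    and digits are token characters; hyphens, en-dashes and all other
    punctuation separate tokens, so "T-cell" and "T cell" produce the same
    token sequence.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isalnum():
            j = i + 1
            while j < n and text[j].isalnum():
                j += 1
            tokens.append(Token(normalize_text(text[i:j]), i, j, section))
            i = j
        else:
            i += 1
    return tokens


# Trailing strings that suppress a sentence boundary after their final period.
ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "vs.", "fig.", "cf.", "ref.", "approx.")

_SENT_PUNCT = re.compile(r"[.!?]")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based, half-open, whitespace-trimmed).

    A boundary is a '.', '!' or '?' followed by whitespace and an uppercase
    letter or digit, unless the text up to the period ends in a known
    abbreviation.  Spans cover all non-whitespace characters.
    """
    boundaries: list[int] = []
    for m in _SENT_PUNCT.finditer(text):
        i = m.end()
        j = i
        while j < len(text) and text[j].isspace():
            j += 1
        if j == i or j >= len(text):
            continue
        if not (text[j].isupper() or text[j].isdigit()):
            continue
        prefix = text[:i].lower()
        if any(prefix.endswith(a) for a in ABBREVIATIONS):
            continue
        boundaries.append(i)

    spans: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        start = prev + (len(seg) - len(seg.lstrip()))
        end = prev + len(seg.rstrip())
        if end > start:
            spans.append((start, end))
        prev = b
    return spans


def sentence_index_of(spans: Sequence[tuple[int, int]], offset: int) -> int:
    """Index of the sentence span containing ``offset`` (nearest span if between)."""
    for idx, (s, e) in enumerate(spans):
        if s <= offset < e:
            return idx
    # offset in inter-span whitespace: attribute to the previous sentence
    for idx in range(len(spans) - 1, -1, -1):
        if spans[idx][0] <= offset:
            return idx
    return 0


def read_jsonl(path) -> Iterator[Document]:
    """Stream documents from a JSONL corpus (one object per line).

    Duplicate PMIDs raise an error naming both offending lines; a record
    without an ``abstract`` key is read with an empty abstract and a warning.
    """
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON: {exc}") from exc
            pmid = str(rec.get("pmid", "")).strip()
            if not pmid:
                raise ValueError(f"line {lineno}: missing pmid")
            if pmid in seen:
                raise ValueError(
                    f"duplicate pmid {pmid} on lines {seen[pmid]} and {lineno}"
                )
            seen[pmid] = lineno
            if "abstract" not in rec:
                warnings.warn(f"line {lineno}: pmid {pmid} has no abstract; treated as empty")
            year = rec.get("year")
            yield Document(
                pmid=pmid,
                title=rec.get("title", "") or "",
                abstract=rec.get("abstract", "") or "",
                year=int(year) if year is not None else None,
                journal=rec.get("journal"),
            )


def write_jsonl(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {"pmid": doc.pmid, "title": doc.title, "abstract": doc.abstract}
            if doc.year is not None:
                rec["year"] = doc.year
            if doc.journal is not None:
                rec["journal"] = doc.journal
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


_YEAR_RE = re.compile(r"(1[89]\d\d|20\d\d|2100)")


def read_pubmed_xml(path) -> Iterator[Document]:
    """Stream documents from PubMed/MEDLINE XML (PubmedArticle records).

    Labeled AbstractText sections are concatenated with a single space.
    Records without a PMID are skipped with a warning.
    """
    tree = etree.parse(str(path))
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid or not pmid.strip():
            warnings.warn("PubmedArticle without PMID skipped")
            continue
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        parts = [
            " ".join("".join(el.itertext()).split())
            for el in art.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in parts if p)
        year: int | None = None
        ytext = art.findtext(".//Article//PubDate/Year")
        if ytext is None:
            mdate = art.findtext(".//Article//PubDate/MedlineDate") or ""
            m = _YEAR_RE.search(mdate)
            ytext = m.group(1) if m else None
        if ytext is not None:
            year = int(ytext)
        yield Document(pmid=pmid.strip(), title=title, abstract=abstract, year=year)


def doc_tokens(doc: Document) -> list[Token]:
    """Title tokens followed by abstract tokens."""
    return normalize_tokens(doc.title, TITLE) + normalize_tokens(doc.abstract, ABSTRACT)


def compute_stats(corpus: Sequence[Document], lexicon=None) -> CorpusStats:
    """Document count, average length, token and (optionally) concept document
    frequencies over title+abstract.

    ``concept_df`` is populated when a lexicon is given, by running the
    dictionary matcher and counting, for each concept, the number of documents
    with at least one mention.
    """
    if len(corpus) == 0:
        raise ValueError("cannot compute statistics for an empty corpus")
    df: Counter[str] = Counter()
    total_len = 0
    for doc in corpus:
        toks = doc_tokens(doc)
        total_len += len(toks)
        df.update({t.surface for t in toks})
    concept_df: Counter[str] = Counter()
    if lexicon is not None:
        from . import ner  # local import: ner depends on this module

        for doc in corpus:
            concept_df.update(ner.distinct_concepts(ner.extract_mentions(doc, lexicon)))
    return CorpusStats(
        n_docs=len(corpus),
        avgdl=total_len / len(corpus),
        df=dict(df),
        concept_df=dict(concept_df),
    )
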