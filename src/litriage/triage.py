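"""Document triage: rank abstracts for a (gene, axis) query.

The final relevance score is a weighted combination of three components,
each min-max normalized to [0, 1] across the candidate set:

* an Okapi BM25 score of the query terms (gene symbol + synonyms + any
  boost keywords) against the abstract,
* a concept-range score — how many distinct axis concepts the dictionary
  matcher finds, relative to the richest candidate, and
* a TF-IDF score over the matched concepts.

Candidates are abstracts that mention the gene, fall inside the requested
date window, match no excluded keyword and are neither explicitly excluded
nor already processed for the same query.  Component weights default to
equal thirds and are configurable per axis.  Ties in the final score break
by year descending then PMID descending, which makes the ranking total and
reproducible.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from collections import Counter
from dataclasses import dataclass, field

from . import ner
from .corpus import CorpusStats, Document, compute_stats, doc_tokens, normalize_tokens
from .vocab import GeneEntry, Lexicon

STATUS_ORDER = {"not_done": 0, "partial": 1, "completed": 2}


@dataclass
class Query:
    """A triage request: which gene, which axis, and the search restrictions."""

    gene: GeneEntry
    axis: str = "BP"
    boost_keywords: list[str] = field(default_factory=list)
    excluded_keywords: list[str] = field(default_factory=list)
    excluded_pmids: set[str] = field(default_factory=set)
    date_from: int | None = None
    date_to: int | None = None
    max_results: int = 20

    def __post_init__(self) -> None:
        if self.max_results < 1:
            raise ValueError("max_results must be >= 1")
        if (
            self.date_from is not None
            and self.date_to is not None
            and self.date_from > self.date_to
        ):
            raise ValueError("date_from must not exceed date_to")

    def key(self) -> tuple[str, str]:
        """History key: gene accession + axis (keyword options do not change it)."""
        return (self.gene.accession, self.axis)


@dataclass
class ScoreWeights:
    """Combination weights plus the BM25 shape parameters."""

    w_bm25: float = 1 / 3
    w_range: float = 1 / 3
    w_tfidf: float = 1 / 3
    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if min(self.w_bm25, self.w_range, self.w_tfidf) < 0:
            raise ValueError("weights must be non-negative")
        if self.w_bm25 + self.w_range + self.w_tfidf <= 0:
            raise ValueError("at least one weight must be positive")
        if self.k1 < 0 or not 0 <= self.b <= 1:
            raise ValueError("require k1 >= 0 and 0 <= b <= 1")


@dataclass
class TriageResult:
    pmid: str
    bm25: float
    range_score: float
    tfidf: float
    final_score: float
    rank: int
    year: int | None = None
    title: str = ""
    status: str = "not_done"


@dataclass
class HistoryStore:
    """Append-only record of processed (query, pmid) pairs.

    Replaying the log reconstructs the processed map exactly; persisted form
    is one JSON entry per line.
    """

    processed: dict[tuple[str, str, str], str] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    @staticmethod
    def _pkey(query_key: tuple[str, str], pmid: str) -> tuple[str, str, str]:
        return (query_key[0], query_key[1], pmid)

    def is_processed(self, query_key: tuple[str, str], pmid: str) -> bool:
        return self._pkey(query_key, pmid) in self.processed

    def apply(self, entry: dict) -> None:
        key = (entry["accession"], entry["axis"], entry["pmid"])
        new = entry["status"]
        old = self.processed.get(key)
        if old is not None and STATUS_ORDER[new] < STATUS_ORDER[old]:
            raise ValueError(
                f"status regression {old} -> {new} for pmid {entry['pmid']}"
            )
        self.processed[key] = new
        self.log.append(entry)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "HistoryStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    store.apply(json.loads(line))
        return store

    @classmethod
    def replay(cls, entries: list[dict]) -> "HistoryStore":
        store = cls()
        for entry in entries:
            store.apply(entry)
        return store


def mark_processed(
    history: HistoryStore, query: Query, pmid: str, status: str = "completed"
) -> HistoryStore:
    """Record a pmid as processed for this query; later triage runs with the
    same (gene, axis) key omit it.  Status transitions are monotone
    (not_done -> partial -> completed); regressions raise."""
    if status not in STATUS_ORDER:
        raise ValueError(f"unknown status {status!r}")
    history.apply(
        {
            "accession": query.gene.accession,
            "axis": query.axis,
            "pmid": pmid,
            "status": status,
            "timestamp": time.time(),
        }
    )
    return history


def expand_query_terms(strings: list[str]) -> list[str]:
    """Flatten query strings into deduplicated normalized tokens, in order."""
    out: list[str] = []
    for s in strings:
        for tok in normalize_tokens(s):
            if tok.surface not in out:
                out.append(tok.surface)
    return out


def bm25_score(
    query_terms: list[str],
    doc: Document,
    stats: CorpusStats,
    k1: float = 1.2,
    b: float = 0.75,
) -> float:
    """Okapi BM25 with the +1-smoothed Robertson idf.

    score = sum_t idf(t) * f(t,d)*(k1+1) / (f(t,d) + k1*(1-b+b*|d|/avgdl))
    with idf(t) = ln(1 + (N - df(t) + 0.5)/(df(t) + 0.5)).  The smoothing
    keeps idf positive even when df > N/2, so scores are always >= 0.
    Terms absent from the corpus contribute 0.
    """
    if not query_terms:
        warnings.warn("bm25_score called with an empty query term list")
        return 0.0
    counts = Counter(t.surface for t in doc_tokens(doc))
    dl = sum(counts.values())
    score = 0.0
    for term in query_terms:
        df = stats.df.get(term, 0)
        f = counts.get(term, 0)
        if df == 0 or f == 0:
            continue
        idf = math.log(1 + (stats.n_docs - df + 0.5) / (df + 0.5))
        score += idf * f * (k1 + 1) / (f + k1 * (1 - b + b * dl / stats.avgdl))
    return score


def distinct_concept_count(doc: Document, lexicon: Lexicon) -> int:
    return len(ner.distinct_concepts(ner.extract_mentions(doc, lexicon)))


def concept_range_score(
    doc: Document, lexicon: Lexicon, candidates: list[Document]
) -> float:
    """Distinct-concept count of ``doc`` relative to the richest candidate.

    Returns 0 when no candidate contains any axis concept.
    """
    peak = max((distinct_concept_count(d, lexicon) for d in candidates), default=0)
    if peak == 0:
        return 0.0
    return distinct_concept_count(doc, lexicon) / peak


def tfidf_doc_score(doc: Document, lexicon: Lexicon, stats: CorpusStats) -> float:
    """Sum over distinct axis concepts of tf(c,d) * ln(N / concept_df(c)).

    tf counts mentions within the document.  A concept observed in the
    document but absent from ``stats.concept_df`` means the statistics are
    stale for this corpus and is an error.
    """
    counts = Counter(m.concept_id for m in ner.extract_mentions(doc, lexicon))
    score = 0.0
    for cid, tf in counts.items():
        df = stats.concept_df.get(cid, 0)
        if df == 0:
            raise ValueError(f"concept {cid} missing from corpus statistics (stale stats?)")
        score += tf * math.log(stats.n_docs / df)
    return score


def _contains_keyword(doc: Document, keyword: str) -> bool:
    """Keyword match = the keyword's normalized token sequence occurs contiguously."""
    key = tuple(t.surface for t in normalize_tokens(keyword))
    if not key:
        return False
    for text in (doc.title, doc.abstract):
        surfaces = [t.surface for t in normalize_tokens(text)]
        for i in range(len(surfaces) - len(key) + 1):
            if tuple(surfaces[i : i + len(key)]) == key:
                return True
    return False


def _minmax(values: list[float]) -> list[float]:
    """Min-max normalize to [0,1]; a constant component maps to all zeros."""
    lo, hi = min(values), max(values)
    if hi - lo <= 0:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def triage(
    query: Query,
    corpus: list[Document],
    lexicon: Lexicon,
    weights: ScoreWeights | None = None,
    history: HistoryStore | None = None,
    stats: CorpusStats | None = None,
) -> list[TriageResult]:
    """Rank the corpus for a query.  Returns at most ``query.max_results``
    results, sorted by combined score (ties: year desc, pmid desc)."""
    weights = weights or ScoreWeights()
    if stats is None:
        stats = compute_stats(corpus, lexicon)

    candidates: list[Document] = []
    for doc in corpus:
        if doc.pmid in query.excluded_pmids:
            continue
        if history is not None and history.is_processed(query.key(), doc.pmid):
            continue
        if query.date_from is not None and (doc.year is None or doc.year < query.date_from):
            continue
        if query.date_to is not None and (doc.year is None or doc.year > query.date_to):
            continue
        if any(_contains_keyword(doc, kw) for kw in query.excluded_keywords):
            continue
        if not ner.find_gene_mentions(doc, query.gene):
            continue
        candidates.append(doc)
    if not candidates:
        return []

    query_terms = expand_query_terms(query.gene.surface_forms() + query.boost_keywords)
    bm25_raw = [bm25_score(query_terms, d, stats, weights.k1, weights.b) for d in candidates]
    counts = [distinct_concept_count(d, lexicon) for d in candidates]
    peak = max(counts)
    range_raw = [c / peak if peak else 0.0 for c in counts]
    tfidf_raw = [tfidf_doc_score(d, lexicon, stats) for d in candidates]

    bm25_n, range_n, tfidf_n = _minmax(bm25_raw), _minmax(range_raw), _minmax(tfidf_raw)
    finals = [
        weights.w_bm25 * bn + weights.w_range * rn + weights.w_tfidf * tn
        for bn, rn, tn in zip(bm25_n, range_n, tfidf_n)
    ]

    def sort_key(i: int):
        doc = candidates[i]
        year = doc.year if doc.year is not None else -1
        pmid_key = int(doc.pmid) if doc.pmid.isdigit() else 0
        return (-finals[i], -year, -pmid_key, doc.pmid)

    order = sorted(range(len(candidates)), key=sort_key)[: query.max_results]
    return [
        TriageResult(
            pmid=candidates[i].pmid,
            bm25=bm25_raw[i],
            range_score=range_raw[i],
            tfidf=tfidf_raw[i],
            final_score=finals[i],
            rank=rank,
            year=candidates[i].year,
            title=candidates[i].title,
        )
        for rank, i in enumerate(order, 1)
    ]


def results_to_tsv(results: list[TriageResult]) -> str:
    lines = ["rank\tpmid\tyear\ttitle\tbm25\trange\ttfidf\tfinal\tstatus"]
    for r in results:
        year = r.year if r.year is not None else ""
        lines.append(
            f"{r.rank}\t{r.pmid}\t{year}\t{r.title}\t{r.bm25:.6f}\t"
            f"{r.range_score:.6f}\t{r.tfidf:.6f}\t{r.final_score:.6f}\t{r.status}"
        )
    return "\n".join(lines) + "\n"
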