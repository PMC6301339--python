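"""Dictionary-based concept extraction with exact offsets.

The matcher slides over the normalized token stream of each section (title,
then abstract) and resolves overlapping dictionary hits by preferring the
longer token span, breaking remaining ties leftmost.  Longer surface forms
are usually the more specific ontology class ("regulation of cell cycle"
beats "cell cycle"), which matches how curators prefer child terms over
parents.  An ambiguous surface form — one string indexed for several
concepts — yields one mention per candidate id, all sharing the same span
and flagged ``ambiguous``; disambiguation is deliberately left to the
curator.  Blacklisted concepts are still extracted here: filtering happens
downstream so the evaluation can count them.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import corpus as corpus_mod
from .corpus import Document, Token, normalize_tokens, sentence_index_of, split_sentences
from .vocab import GeneEntry, Lexicon, SurfaceKey, normalize_surface


@dataclass(frozen=True)
class ConceptMention:
    """One matched surface form, located by section, offsets and sentence."""

    concept_id: str
    matched_surface: str
    section: str
    start: int  # 0-based character offset into the section text
    end: int    # exclusive
    sentence_index: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("mention span must be non-empty")


def _match_section(
    text: str,
    tokens: list[Token],
    index: dict[SurfaceKey, set[str]],
    max_len: int,
    section: str,
) -> list[ConceptMention]:
    """All dictionary hits in one section, overlaps resolved longest-then-leftmost."""
    if not tokens or not index:
        return []
    surfaces = [t.surface for t in tokens]
    hits: list[tuple[int, int]] = []  # (token start index, token length)
    for i in range(len(tokens)):
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            if tuple(surfaces[i : i + length]) in index:
                hits.append((i, length))
    # longer spans first, then leftmost; keep spans disjoint in token space
    hits.sort(key=lambda h: (-h[1], h[0]))
    occupied: set[int] = set()
    kept: list[tuple[int, int]] = []
    for i, length in hits:
        span = range(i, i + length)
        if any(t in occupied for t in span):
            continue
        occupied.update(span)
        kept.append((i, length))
    kept.sort()

    sent_spans = split_sentences(text)
    mentions: list[ConceptMention] = []
    for i, length in kept:
        start = tokens[i].start
        end = tokens[i + length - 1].end
        ids = sorted(index[tuple(surfaces[i : i + length])])
        for cid in ids:
            mentions.append(
                ConceptMention(
                    concept_id=cid,
                    matched_surface=text[start:end],
                    section=section,
                    start=start,
                    end=end,
                    sentence_index=sentence_index_of(sent_spans, start),
                    ambiguous=len(ids) > 1,
                )
            )
    return mentions


def extract_mentions(
    doc: Document, lexicon: Lexicon, include_title: bool = True
) -> list[ConceptMention]:
    """Extract concept mentions from a document (title first, then abstract)."""
    max_len = lexicon.max_key_len()
    sections = []
    if include_title:
        sections.append((corpus_mod.TITLE, doc.title))
    sections.append((corpus_mod.ABSTRACT, doc.abstract))
    mentions: list[ConceptMention] = []
    for section, text in sections:
        tokens = normalize_tokens(text, section)
        mentions.extend(_match_section(text, tokens, lexicon.surface_index, max_len, section))
    return mentions


def distinct_concepts(mentions: list[ConceptMention]) -> list[str]:
    """Unique concept ids ordered by first occurrence (title before abstract)."""
    return list(dict.fromkeys(m.concept_id for m in mentions))


def find_gene_mentions(doc: Document, gene: GeneEntry, include_title: bool = True) -> list[ConceptMention]:
    """Locate mentions of a gene's symbol or synonyms, resolving to its accession."""
    index: dict[SurfaceKey, set[str]] = {}
    for surface in gene.surface_forms():
        key = normalize_surface(surface)
        if key:
            index.setdefault(key, set()).add(gene.accession)
    max_len = max((len(k) for k in index), default=0)
    sections = []
    if include_title:
        sections.append((corpus_mod.TITLE, doc.title))
    sections.append((corpus_mod.ABSTRACT, doc.abstract))
    mentions: list[ConceptMention] = []
    for section, text in sections:
        tokens = normalize_tokens(text, section)
        mentions.extend(_match_section(text, tokens, index, max_len, section))
    return mentions


def mentions_to_tsv(pmid: str, mentions: list[ConceptMention]) -> str:
    """Serialize mentions to TSV (pmid, concept_id, section, start, end, sentence_index, surface)."""
    lines = ["pmid\tconcept_id\tsection\tstart\tend\tsentence_index\tsurface"]
    for m in mentions:
        lines.append(
            f"{pmid}\t{m.concept_id}\t{m.section}\t{m.start}\t{m.end}\t{m.sentence_index}\t{m.matched_surface}"
        )
    return "\n".join(lines) + "\n"
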