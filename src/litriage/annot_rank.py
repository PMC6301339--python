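"""Annotation candidates: triplet generation, blacklist filtering, TF-IDF
re-ranking and the accept/modify/reject review semantics.

A candidate is a curation triplet — subject protein, relation, concept
object — plus an evidence code (ECO) and provenance (PMID, sentence, span).
Two orderings are offered: the *linear view* follows the position of the
first mention in the text; the *ranked view* sorts by a TF-IDF importance
score, where tf counts how many retrieved abstracts mention the concept and
idf down-weights concepts frequent in a large background document sample,
so vague everyday terms drop to the bottom of the list.

Review rules: editing the relation or the evidence code alone still counts
as *accepted*; a *modification* replaces the concept with another term in
the same ontology branch (shares a non-root is_a ancestor); anything else
is a *rejection*.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

from . import ner
from .corpus import Document
from .vocab import Lexicon

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = {"BP": "is involved in", "D": "is associated with"}
DEFAULT_ECO = "ECO:0000305"

_SECTION_ORDER = {"title": 0, "abstract": 1}


@dataclass(frozen=True)
class AnnotationCandidate:
    subject: str
    relation: str
    object_id: str
    eco: str
    pmid: str
    section: str
    sentence_index: int
    start: int
    end: int
    rank_score: float = 0.0
    status: str = "pending"
    modified_object_id: str | None = None

    def __post_init__(self) -> None:
        if self.status == "modified" and (
            self.modified_object_id is None or self.modified_object_id == self.object_id
        ):
            raise ValueError("modified candidate needs a distinct modified_object_id")


def generate_candidates(
    doc: Document,
    mentions: list[ner.ConceptMention],
    gene_mentions: list[ner.ConceptMention],
    subject: str,
    axis: str = "BP",
    relation: str | None = None,
    eco: str | None = None,
) -> list[AnnotationCandidate]:
    """One pending candidate per distinct concept, in text order.

    A document without a gene mention yields no candidates.  Provenance
    (sentence, span) comes from the concept's first mention; relation and
    evidence code start at the axis defaults and stay editable at review.
    """
    if not gene_mentions:
        return []
    relation = relation if relation is not None else DEFAULT_RELATIONS.get(axis, "is related to")
    eco = eco if eco is not None else DEFAULT_ECO
    ordered = sorted(
        mentions, key=lambda m: (_SECTION_ORDER.get(m.section, 2), m.start)
    )
    seen: set[str] = set()
    candidates: list[AnnotationCandidate] = []
    for m in ordered:
        if m.concept_id in seen or m.concept_id == subject:
            continue
        seen.add(m.concept_id)
        candidates.append(
            AnnotationCandidate(
                subject=subject,
                relation=relation,
                object_id=m.concept_id,
                eco=eco,
                pmid=doc.pmid,
                section=m.section,
                sentence_index=m.sentence_index,
                start=m.start,
                end=m.end,
            )
        )
    return candidates


def apply_blacklist(
    candidates: list[AnnotationCandidate], lexicon: Lexicon
) -> list[AnnotationCandidate]:
    """Drop candidates whose object is blacklisted; the removal count is logged."""
    kept = [c for c in candidates if c.object_id not in lexicon.blacklist]
    removed = len(candidates) - len(kept)
    if removed:
        logger.info("blacklist removed %d of %d candidates", removed, len(candidates))
    return kept


def tfidf_rank(
    candidates: list[AnnotationCandidate],
    retrieved_docs: list[Document],
    background_df: dict[str, int],
    background_n: int,
    lexicon: Lexicon,
) -> list[AnnotationCandidate]:
    """Re-rank candidates by TF-IDF importance (the "ranked view").

    rank_score(c) = tf(c) * ln((background_n + 1) / (background_df(c) + 1)),
    where tf(c) counts the retrieved documents mentioning concept c.  The
    +1 smoothing keeps concepts unseen in the background sample rankable
    (they get the maximal idf, with a warning).  Equal scores preserve text
    order.
    """
    doc_concepts = [
        set(ner.distinct_concepts(ner.extract_mentions(d, lexicon)))
        for d in retrieved_docs
    ]
    ranked: list[AnnotationCandidate] = []
    for cand in candidates:
        tf = sum(cand.object_id in concepts for concepts in doc_concepts)
        if cand.object_id not in background_df:
            warnings.warn(
                f"concept {cand.object_id} missing from background frequencies; df=0 assumed"
            )
        df = background_df.get(cand.object_id, 0)
        score = tf * math.log((background_n + 1) / (df + 1))
        ranked.append(replace(cand, rank_score=score))
    ranked.sort(key=lambda c: -c.rank_score)  # stable: ties keep text order
    return ranked


def review(
    candidate: AnnotationCandidate,
    action: str,
    new_object: str | None = None,
    new_relation: str | None = None,
    new_eco: str | None = None,
    lexicon: Lexicon | None = None,
) -> AnnotationCandidate:
    """Apply a curator decision to a pending candidate.

    * ``accept``: relation/ECO edits are allowed and do not change the action;
      the concept stays as proposed.
    * ``modify``: requires ``new_object`` distinct from the proposal and in
      the same ontology branch (shared non-root is_a ancestor).
    * ``reject``: the proposal is discarded as an annotation but kept, with
      status ``rejected``, for the evaluation counts.
    """
    if candidate.status != "pending":
        raise ValueError(f"candidate already reviewed (status={candidate.status})")
    relation = new_relation if new_relation is not None else candidate.relation
    eco = new_eco if new_eco is not None else candidate.eco
    if action == "accept":
        return replace(candidate, relation=relation, eco=eco, status="accepted")
    if action == "reject":
        return replace(candidate, relation=relation, eco=eco, status="rejected")
    if action == "modify":
        if new_object is None:
            raise ValueError("modify requires a replacement concept")
        if new_object == candidate.object_id:
            raise ValueError("modify requires a concept different from the proposal")
        if lexicon is None:
            raise ValueError("modify requires the lexicon for the branch check")
        if new_object not in lexicon.concepts:
            raise ValueError(f"unknown replacement concept {new_object}")
        if not lexicon.same_branch(candidate.object_id, new_object):
            raise ValueError(
                f"{new_object} is outside the ontology branch of {candidate.object_id}"
            )
        return replace(
            candidate,
            relation=relation,
            eco=eco,
            status="modified",
            modified_object_id=new_object,
        )
    raise ValueError(f"unknown review action {action!r}")


def candidates_to_tsv(candidates: list[AnnotationCandidate], lexicon: Lexicon | None = None) -> str:
    lines = [
        "subject\trelation\tobject_id\tobject_label\teco\tpmid\tsection\t"
        "sentence_index\tstart\tend\trank_score\tstatus"
    ]
    for c in candidates:
        label = ""
        if lexicon is not None and c.object_id in lexicon.concepts:
            label = lexicon.label_of(c.object_id)
        lines.append(
            f"{c.subject}\t{c.relation}\t{c.object_id}\t{label}\t{c.eco}\t{c.pmid}\t"
            f"{c.section}\t{c.sentence_index}\t{c.start}\t{c.end}\t{c.rank_score:.6f}\t{c.status}"
        )
    return "\n".join(lines) + "\n"
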