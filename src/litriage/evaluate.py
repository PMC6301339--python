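"""Evaluation metrics for triage and concept extraction.

Covers the full battery used to assess a curation-support pipeline against
dual-curator judgments:

* triage inter-annotator agreement (both-accept / both-reject / split),
* concept-extraction precision from accepted/modified/rejected counts,
* concept recall against curator gold sets, with *semantic classes* as the
  equivalence unit — near-synonymous ontology terms are manually grouped per
  abstract, because hierarchy distance is a poor proxy for "same finding",
* per-abstract concept agreement between two curators (Jaccard on classes),
* precision-at-rank (P0 = precision at rank 1, P5 over the top five, with
  the TREC convention of a fixed denominator k), and relative gain between a
  baseline and an improved ranking,
* per-term rejection tables that surface always-rejected, blacklistable terms.

All integer percentages use round-half-up, which reproduces standard
published contingency tables (e.g. 162/242 -> 67, 699/3175 -> 22).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .vocab import Lexicon


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero for positive values."""
    return math.floor(x + 0.5)


def pct(numerator: float, denominator: float) -> int:
    """Integer percentage, round half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


@dataclass
class CurationDecision:
    """One curator's judgment on one abstract: triage relevance plus the
    concept set they extracted (empty when judged irrelevant)."""

    curator_id: str
    pmid: str
    axis: str
    relevant: bool
    concepts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.relevant and self.concepts:
            raise ValueError(
                f"pmid {self.pmid}: concepts present on an irrelevant decision"
            )


@dataclass
class ReviewCounts:
    """Accepted/modified/rejected counts for a batch of proposed annotations."""

    total: int
    accepted: int
    modified: int
    rejected: int

    def __post_init__(self) -> None:
        if min(self.total, self.accepted, self.modified, self.rejected) < 0:
            raise ValueError("counts must be non-negative")
        # Published tables occasionally print a total that differs slightly
        # from the action sum; the total stays the denominator, but a large
        # discrepancy is a data error.
        diff = abs(self.accepted + self.modified + self.rejected - self.total)
        if diff > max(2, 0.01 * self.total):
            raise ValueError("accepted + modified + rejected must equal total")
        if diff:
            warnings.warn(
                f"review counts sum to {self.accepted + self.modified + self.rejected}"
                f" but total is {self.total}; total kept as denominator"
            )


def triage_agreement(
    dec_a: dict[str, bool], dec_b: dict[str, bool]
) -> dict[str, int]:
    """Two-curator triage contingency over a shared pmid set.

    Returns counts and round-half-up integer percentages; ``agreement_pct``
    is the percentage of abstracts where both curators made the same call.
    """
    if set(dec_a) != set(dec_b):
        only_a = sorted(set(dec_a) - set(dec_b))
        only_b = sorted(set(dec_b) - set(dec_a))
        raise ValueError(
            f"curator pmid sets differ (only A: {only_a}, only B: {only_b})"
        )
    if not dec_a:
        raise ValueError("no decisions to compare")
    both_accept = sum(dec_a[p] and dec_b[p] for p in dec_a)
    both_reject = sum(not dec_a[p] and not dec_b[p] for p in dec_a)
    total = len(dec_a)
    split = total - both_accept - both_reject
    return {
        "both_accept": both_accept,
        "both_reject": both_reject,
        "split": split,
        "total": total,
        "pct_accept": pct(both_accept, total),
        "pct_reject": pct(both_reject, total),
        "pct_split": pct(split, total),
        "agreement_pct": pct(both_accept + both_reject, total),
    }


def concept_precision(counts: ReviewCounts) -> int:
    """Percentage of proposed descriptors accepted or modified by curators."""
    if counts.total == 0:
        raise ValueError("precision undefined for zero proposals")
    return pct(counts.accepted + counts.modified, counts.total)


def _classes_of(
    concepts: set[str], pmid: str, classmap: dict[str, dict[str, int]]
) -> set[int]:
    pmid_map = classmap.get(pmid, {})
    out: set[int] = set()
    for cid in concepts:
        if cid not in pmid_map:
            raise KeyError(f"pmid {pmid}: concept {cid} has no semantic class")
        out.add(pmid_map[cid])
    return out


def concept_recall(
    system: dict[str, set[str]],
    dec_a: dict[str, CurationDecision],
    dec_b: dict[str, CurationDecision],
    classmap: dict[str, dict[str, int]],
    mode: str = "either",
) -> float:
    """Recall of the system's concepts against curator gold sets, pooled over
    abstracts at the semantic-class level.

    ``mode='both'`` takes as gold the classes of concepts found by both
    curators; ``mode='either'`` those found by at least one.  A gold class is
    recalled when the system proposes any concept of that class for that
    abstract.  Equivalence is always class-level, never raw-id-level.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    gold_total = 0
    gold_hit = 0
    for pmid in sorted(set(dec_a) & set(dec_b)):
        ca = _classes_of(dec_a[pmid].concepts, pmid, classmap)
        cb = _classes_of(dec_b[pmid].concepts, pmid, classmap)
        gold = ca & cb if mode == "both" else ca | cb
        if not gold:
            continue
        sys_classes = _classes_of(system.get(pmid, set()), pmid, classmap)
        gold_total += len(gold)
        gold_hit += len(gold & sys_classes)
    if gold_total == 0:
        raise ValueError("no gold classes to evaluate")
    return 100.0 * gold_hit / gold_total


def iaa_concepts(
    dec_a: dict[str, CurationDecision],
    dec_b: dict[str, CurationDecision],
    classmap: dict[str, dict[str, int]],
) -> dict:
    """Concept-level inter-annotator agreement.

    Per abstract: the proportion of semantic classes annotated by both
    curators among classes annotated by either (Jaccard).  Reports the mean
    over abstracts, the percentage of abstracts with at least one common
    class, and the histogram of common-class counts.  Abstracts where
    neither curator annotated anything are excluded with a warning.
    """
    agreements: list[float] = []
    common_hist: Counter[int] = Counter()
    n_with_common = 0
    n_scored = 0
    excluded: list[str] = []
    for pmid in sorted(set(dec_a) & set(dec_b)):
        ca = _classes_of(dec_a[pmid].concepts, pmid, classmap)
        cb = _classes_of(dec_b[pmid].concepts, pmid, classmap)
        union = ca | cb
        if not union:
            excluded.append(pmid)
            continue
        common = len(ca & cb)
        n_scored += 1
        common_hist[common] += 1
        if common >= 1:
            n_with_common += 1
        agreements.append(100.0 * common / len(union))
    if excluded:
        warnings.warn(
            f"{len(excluded)} abstract(s) with no concepts from either curator "
            f"excluded (first: {excluded[0]})"
        )
    if n_scored == 0:
        raise ValueError("no abstracts with concepts to compare")
    return {
        "n_abstracts": n_scored,
        "n_with_common_term": n_with_common,
        "pct_abstracts_with_common_term": pct(n_with_common, n_scored),
        "mean_agreement_pct": sum(agreements) / len(agreements),
        "common_count_histogram": dict(sorted(common_hist.items())),
    }


def precision_at_rank(
    judgments: dict[str, list[tuple[str, bool]]], k: int = 1
) -> float:
    """Mean precision of the top-k proposed concepts over abstracts.

    k=1 is the precision at first rank (P0); for k>1 the denominator is
    fixed at k even when fewer candidates exist (TREC convention).  An
    abstract with an empty list contributes 0 correct over the same
    denominator.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not judgments:
        raise ValueError("no ranked judgments given")
    total = 0.0
    for ranked in judgments.values():
        correct = sum(ok for _, ok in ranked[:k])
        total += correct / k
    return total / len(judgments)


def relative_gain(baseline: float, improved: float) -> int:
    """Signed integer percentage gain of ``improved`` over ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round_half_up(100.0 * (improved - baseline) / baseline)


def descriptor_ratio(system_avg: float, curator_avg: float) -> float:
    """How many times more descriptors the system proposes than curators
    extract, to one decimal (round half-up)."""
    if curator_avg <= 0:
        raise ValueError("curator average must be positive")
    return round_half_up(10.0 * system_avg / curator_avg) / 10.0


def term_rejection_table(
    reviews: list[tuple[str, str]],
    lexicon: Lexicon | None = None,
    min_total: int = 30,
) -> pd.DataFrame:
    """Per-concept review outcome table, sorted by rejection count.

    ``reviews`` is a flat list of (concept id, action) with action in
    accepted/modified/rejected.  Concepts proposed fewer than ``min_total``
    times are dropped; concepts rejected every time are flagged
    ``always_rejected`` — prime blacklist candidates.
    """
    per_concept: dict[str, Counter[str]] = {}
    for cid, action in reviews:
        if action not in ("accepted", "modified", "rejected"):
            raise ValueError(f"unknown review action {action!r}")
        per_concept.setdefault(cid, Counter())[action] += 1
    rows = []
    for cid, counts in per_concept.items():
        total = sum(counts.values())
        if total < min_total:
            continue
        rejected = counts["rejected"]
        rows.append(
            {
                "concept_id": cid,
                "label": lexicon.label_of(cid)
                if lexicon is not None and cid in lexicon.concepts
                else "",
                "rejected": rejected,
                "rejected_pct": pct(rejected, total),
                "modified": counts["modified"],
                "modified_pct": pct(counts["modified"], total),
                "accepted": counts["accepted"],
                "accepted_pct": pct(counts["accepted"], total),
                "total": total,
                "always_rejected": rejected == total,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "concept_id", "label", "rejected", "rejected_pct", "modified",
            "modified_pct", "accepted", "accepted_pct", "total", "always_rejected",
        ],
    )
    if len(frame):
        frame = frame.sort_values(
            ["rejected", "concept_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


# --- judgment / class-map file I/O --------------------------------------


def load_judgments(path) -> dict[str, CurationDecision]:
    """Read a curator judgment TSV (curator_id, pmid, axis, relevant,
    concept_ids semicolon-separated) into a pmid-keyed map."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("curator_id", "pmid", "axis", "relevant", "concept_ids")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"judgments {path}: missing column(s) {', '.join(missing)}")
    out: dict[str, CurationDecision] = {}
    for idx, row in frame.iterrows():
        relevant = row["relevant"].strip().lower() in ("1", "true", "yes")
        concepts = {c.strip() for c in row["concept_ids"].split(";") if c.strip()}
        out[row["pmid"]] = CurationDecision(
            curator_id=row["curator_id"],
            pmid=row["pmid"],
            axis=row["axis"],
            relevant=relevant,
            concepts=concepts if relevant else set(),
        )
    return out


def load_classmap(path) -> dict[str, dict[str, int]]:
    """Read a semantic-class map TSV (pmid, concept_id, class)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("pmid", "concept_id", "class") if c not in frame.columns]
    if missing:
        raise ValueError(f"class map {path}: missing column(s) {', '.join(missing)}")
    out: dict[str, dict[str, int]] = {}
    for _, row in frame.iterrows():
        out.setdefault(row["pmid"], {})[row["concept_id"]] = int(row["class"])
    return out


def decisions_to_relevance(decisions: dict[str, CurationDecision]) -> dict[str, bool]:
    return {pmid: d.relevant for pmid, d in decisions.items()}


def extend_classmap(
    classmap: dict[str, dict[str, int]], system: dict[str, set[str]]
) -> dict[str, dict[str, int]]:
    """Return a classmap that also covers system-proposed concepts.

    Concepts absent from the manual map get fresh singleton classes (they
    match nothing the curators chose, so they can only hurt precision,
    never inflate recall)."""
    out = {pmid: dict(m) for pmid, m in classmap.items()}
    for pmid, concepts in system.items():
        pmid_map = out.setdefault(pmid, {})
        next_class = max(pmid_map.values(), default=0) + 1
        for cid in sorted(concepts):
            if cid not in pmid_map:
                pmid_map[cid] = next_class
                next_class += 1
    return out
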