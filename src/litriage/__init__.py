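"""litriage: a desk-scale curation-support toolkit.

Given a gene and an annotation axis (GO biological process or disease), the
package ranks abstracts for curation (BM25 + concept range + TF-IDF),
extracts ontology concepts by dictionary matching with exact offsets, turns
them into reviewable annotation triplets with blacklist filtering and
TF-IDF re-ranking, and evaluates the whole pipeline with standard curation
metrics (inter-annotator agreement, precision/recall under semantic-class
equivalence, precision-at-rank, relative gain).
"""

from . import annot_rank, corpus, evaluate, ner, synth, triage, vocab

__version__ = "0.1.0"

__all__ = [
    "annot_rank",
    "corpus",
    "evaluate",
    "ner",
    "synth",
    "triage",
    "vocab",
    "reference_metrics",
    "load_reference_counts",
]


def load_reference_counts() -> dict:
    """Bundled dual-curator benchmark counts (raw counts only; every derived
    percentage is recomputed by the evaluate module)."""
    import json
    from importlib import resources

    with resources.files("litriage.data").joinpath("benchmark_counts.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def reference_metrics() -> dict:
    """Recompute every derivable metric from the bundled benchmark counts.

    Each value is produced by the corresponding evaluate-module operation on
    the raw counts: triage contingency percentages and agreement, concept
    precision, common-term rates, descriptor ratios and re-ranking gains.
    """
    counts = load_reference_counts()
    out: dict[str, dict] = {}
    for axis in ("BP", "D"):
        tri = counts["triage_agreement"][axis]
        dec_a, dec_b = _contingency_decisions(
            tri["both_accept"], tri["both_reject"], tri["split"]
        )
        agreement = evaluate.triage_agreement(dec_a, dec_b)

        rev = counts["concept_review"][axis]
        total = rev["total"]
        review = evaluate.ReviewCounts(
            total=total,
            accepted=rev["accepted"],
            modified=rev["modified"],
            rejected=rev["rejected"],
        )

        common = counts["common_term_counts"][axis]
        iaa = evaluate.iaa_concepts(*_common_term_decisions(common["with_common"], common["total"]))

        terms = counts["terms_per_abstract"][axis]
        rank = counts["rank_precision"][axis]
        out[axis] = {
            "triage": agreement,
            "accepted_pct": evaluate.pct(rev["accepted"], total),
            "modified_pct": evaluate.pct(rev["modified"], total),
            "rejected_pct": evaluate.pct(rev["rejected"], total),
            "concept_precision_pct": evaluate.concept_precision(review),
            "pct_abstracts_with_common_term": iaa["pct_abstracts_with_common_term"],
            "descriptor_ratio": evaluate.descriptor_ratio(terms["system"], terms["curator"]),
            "gain_p0": evaluate.relative_gain(rank["baseline_p0"], rank["reranked_p0"]),
            "gain_p5": evaluate.relative_gain(rank["baseline_p5"], rank["reranked_p5"]),
        }
    return out


def _contingency_decisions(both_accept: int, both_reject: int, split: int):
    """Materialize two curators' triage decisions realizing a contingency table."""
    dec_a: dict[str, bool] = {}
    dec_b: dict[str, bool] = {}
    i = 0
    for _ in range(both_accept):
        dec_a[str(i)], dec_b[str(i)] = True, True
        i += 1
    for _ in range(both_reject):
        dec_a[str(i)], dec_b[str(i)] = False, False
        i += 1
    for j in range(split):
        dec_a[str(i)], dec_b[str(i)] = (j % 2 == 0), (j % 2 == 1)
        i += 1
    return dec_a, dec_b


def _common_term_decisions(with_common: int, total: int):
    """Materialize per-abstract concept sets realizing a common-term count."""
    dec_a: dict[str, evaluate.CurationDecision] = {}
    dec_b: dict[str, evaluate.CurationDecision] = {}
    classmap: dict[str, dict[str, int]] = {}
    for i in range(total):
        pmid = str(i)
        if i < with_common:
            a, b = {"X"}, {"X"}
            classmap[pmid] = {"X": 1}
        else:
            a, b = {"X"}, {"Y"}
            classmap[pmid] = {"X": 1, "Y": 2}
        dec_a[pmid] = evaluate.CurationDecision("A", pmid, "BP", True, a)
        dec_b[pmid] = evaluate.CurationDecision("B", pmid, "BP", True, b)
    return dec_a, dec_b, classmap
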