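"""BM25, component scores, candidate filtering, ranking and history."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from litriage import triage as tri
from litriage.corpus import Document, compute_stats
from litriage.triage import (
    HistoryStore,
    Query,
    ScoreWeights,
    bm25_score,
    concept_range_score,
    mark_processed,
    tfidf_doc_score,
    triage,
)
from litriage.vocab import GeneEntry


def brute_force_bm25(query_terms, doc_words, corpus_words, k1, b):
    """Independent BM25 from first principles over word lists."""
    n = len(corpus_words)
    avgdl = sum(len(w) for w in corpus_words) / n
    dl = len(doc_words)
    score = 0.0
    for t in query_terms:
        df = sum(t in words for words in corpus_words)
        f = doc_words.count(t)
        if df == 0 or f == 0:
            continue
        idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
        score += idf * (f * (k1 + 1)) / (f + k1 * (1 - b + b * dl / avgdl))
    return score


class TestBm25:
    def test_no_term_overlap_scores_zero(self):
        docs = [Document(pmid="1", abstract="alpha beta"), Document(pmid="2", abstract="gamma")]
        stats = compute_stats(docs)
        assert bm25_score(["delta"], docs[0], stats) == 0.0

    def test_empty_query_warns_and_scores_zero(self):
        docs = [Document(pmid="1", abstract="alpha")]
        stats = compute_stats(docs)
        with pytest.warns(UserWarning):
            assert bm25_score([], docs[0], stats) == 0.0

    def test_k1_zero_limit_is_presence_weighted_idf(self):
        docs = [
            Document(pmid="1", abstract="alpha alpha alpha beta"),
            Document(pmid="2", abstract="beta gamma"),
            Document(pmid="3", abstract="gamma gamma"),
        ]
        stats = compute_stats(docs)
        got = bm25_score(["alpha", "beta", "zeta"], docs[0], stats, k1=1e-6, b=0.0)
        n = stats.n_docs
        expected = sum(
            math.log(1 + (n - stats.df[t] + 0.5) / (stats.df[t] + 0.5))
            for t in ("alpha", "beta")  # presence indicator, freq saturates
        )
        assert got == pytest.approx(expected, rel=1e-4)

    def test_matches_brute_force_on_toy_corpus(self):
        corpus_words = [
            ["zap70", "kinase", "cell"],
            ["kinase", "pathway", "pathway"],
            ["cell", "cycle", "zap70", "zap70"],
        ]
        docs = [
            Document(pmid=str(i), abstract=" ".join(w))
            for i, w in enumerate(corpus_words)
        ]
        stats = compute_stats(docs)
        for i, doc in enumerate(docs):
            got = bm25_score(["zap70", "kinase"], doc, stats, k1=1.2, b=0.75)
            want = brute_force_bm25(["zap70", "kinase"], corpus_words[i], corpus_words, 1.2, 0.75)
            assert got == pytest.approx(want)

    @given(
        corpus_words=st.lists(
            st.lists(st.sampled_from("abcdef"), min_size=1, max_size=6),
            min_size=1,
            max_size=4,
        ),
        query=st.lists(st.sampled_from("abcdef"), min_size=1, max_size=3),
        k1=st.floats(0.0, 3.0),
        b=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_all_small_corpora(self, corpus_words, query, k1, b):
        docs = [
            Document(pmid=str(i), abstract=" ".join(w))
            for i, w in enumerate(corpus_words)
        ]
        stats = compute_stats(docs)
        for i, doc in enumerate(docs):
            got = bm25_score(query, doc, stats, k1=k1, b=b)
            want = brute_force_bm25(query, corpus_words[i], corpus_words, k1, b)
            assert got == pytest.approx(want, abs=1e-12)
            assert got >= 0.0


class TestComponentScores:
    def test_range_zero_without_concepts(self, bp_lexicon):
        doc = Document(pmid="1", abstract="no relevant words")
        rich = Document(pmid="2", abstract="autophagy and phosphorylation")
        assert concept_range_score(doc, bp_lexicon, [doc, rich]) == 0.0

    def test_range_relative_to_richest_candidate(self, bp_lexicon):
        half = Document(pmid="1", abstract="autophagy here")
        rich = Document(pmid="2", abstract="autophagy with phosphorylation")
        assert concept_range_score(half, bp_lexicon, [half, rich]) == 0.5
        assert concept_range_score(rich, bp_lexicon, [half, rich]) == 1.0

    def test_single_candidate_self_normalizes(self, bp_lexicon):
        doc = Document(pmid="1", abstract="autophagy here")
        assert concept_range_score(doc, bp_lexicon, [doc]) == 1.0

    def test_tfidf_zero_without_concepts(self, bp_lexicon):
        docs = [
            Document(pmid="1", abstract="nothing"),
            Document(pmid="2", abstract="autophagy"),
        ]
        stats = compute_stats(docs, bp_lexicon)
        assert tfidf_doc_score(docs[0], bp_lexicon, stats) == 0.0

    def test_tfidf_ubiquitous_concept_contributes_zero(self, bp_lexicon):
        docs = [Document(pmid=str(i), abstract="autophagy study") for i in range(3)]
        stats = compute_stats(docs, bp_lexicon)
        assert tfidf_doc_score(docs[0], bp_lexicon, stats) == pytest.approx(0.0)

    def test_tfidf_hand_computed(self, bp_lexicon):
        # concept in 2 of 4 docs, mentioned twice in doc 1: tf*ln(N/df) = 2 ln 2
        docs = [
            Document(pmid="1", abstract="autophagy and more autophagy"),
            Document(pmid="2", abstract="autophagy once"),
            Document(pmid="3", abstract="other text"),
            Document(pmid="4", abstract="other again"),
        ]
        stats = compute_stats(docs, bp_lexicon)
        assert tfidf_doc_score(docs[0], bp_lexicon, stats) == pytest.approx(
            2 * math.log(2)
        )

    def test_stale_stats_detected(self, bp_lexicon):
        docs = [Document(pmid="1", abstract="plain text")]
        stats = compute_stats(docs, bp_lexicon)
        fresh = Document(pmid="2", abstract="autophagy appeared later")
        with pytest.raises(ValueError, match="stale"):
            tfidf_doc_score(fresh, bp_lexicon, stats)


def corpus_with_gene(gene, n=6):
    concepts = ["autophagy", "phosphorylation", "apoptotic process"]
    docs = []
    for i in range(n):
        planted = " and ".join(concepts[: (i % 3) + 1])
        docs.append(
            Document(
                pmid=str(100 + i),
                title=f"Study {i}",
                abstract=f"We measured {gene.symbol} while {planted} occurred.",
                year=2000 + i,
            )
        )
    return docs


class TestTriage:
    def test_pure_bm25_weights_reduce_to_bm25_order(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        stats = compute_stats(docs, bp_lexicon)
        weights = ScoreWeights(w_bm25=1, w_range=0, w_tfidf=0)
        results = triage(Query(gene=gene, max_results=10), docs, bp_lexicon, weights)
        terms = tri.expand_query_terms(gene.surface_forms())
        by_bm25 = sorted(
            docs,
            key=lambda d: (
                -bm25_score(terms, d, stats),
                -(d.year or -1),
                -int(d.pmid),
            ),
        )
        assert [r.pmid for r in results] == [d.pmid for d in by_bm25]

    def test_excluded_pmid_never_appears(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        query = Query(gene=gene, excluded_pmids={"101"}, max_results=10)
        results = triage(query, docs, bp_lexicon)
        assert "101" not in {r.pmid for r in results}

    def test_excluded_keyword_shrinks_candidates(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        base = triage(Query(gene=gene, max_results=10), docs, bp_lexicon)
        narrowed = triage(
            Query(gene=gene, excluded_keywords=["autophagy"], max_results=10),
            docs,
            bp_lexicon,
        )
        assert set(r.pmid for r in narrowed) <= set(r.pmid for r in base)
        assert len(narrowed) < len(base)

    def test_date_window_filters(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        results = triage(
            Query(gene=gene, date_from=2002, date_to=2003, max_results=10),
            docs,
            bp_lexicon,
        )
        assert {r.year for r in results} <= {2002, 2003}

    def test_docs_without_gene_are_not_candidates(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene) + [
            Document(pmid="999", abstract="autophagy without the protein", year=2020)
        ]
        results = triage(Query(gene=gene, max_results=20), docs, bp_lexicon)
        assert "999" not in {r.pmid for r in results}

    def test_scores_monotone_and_ranks_consecutive(self, bp_lexicon, gene):
        results = triage(
            Query(gene=gene, max_results=10), corpus_with_gene(gene), bp_lexicon
        )
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        finals = [r.final_score for r in results]
        assert finals == sorted(finals, reverse=True)

    def test_weight_scale_invariance(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        a = triage(
            Query(gene=gene, max_results=10), docs, bp_lexicon,
            ScoreWeights(0.2, 0.3, 0.5),
        )
        b = triage(
            Query(gene=gene, max_results=10), docs, bp_lexicon,
            ScoreWeights(2.0, 3.0, 5.0),
        )
        assert [r.pmid for r in a] == [r.pmid for r in b]

    def test_empty_candidate_set_is_empty_result(self, bp_lexicon, gene):
        docs = [Document(pmid="1", abstract="no gene at all")]
        assert triage(Query(gene=gene), docs, bp_lexicon) == []

    def test_max_results_truncates(self, bp_lexicon, gene):
        results = triage(
            Query(gene=gene, max_results=2), corpus_with_gene(gene), bp_lexicon
        )
        assert len(results) == 2


class TestHistory:
    def test_marked_pmid_disappears_for_same_query(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        history = HistoryStore()
        query = Query(gene=gene, max_results=10)
        first = triage(query, docs, bp_lexicon, history=history)
        mark_processed(history, query, first[0].pmid, "completed")
        second = triage(query, docs, bp_lexicon, history=history)
        assert first[0].pmid not in {r.pmid for r in second}

    def test_history_is_per_query_key(self, bp_lexicon, gene):
        docs = corpus_with_gene(gene)
        history = HistoryStore()
        query = Query(gene=gene, max_results=10)
        mark_processed(history, query, "100", "completed")
        other_gene = GeneEntry("NX_P43405", "SYK", [])
        docs_syk = [
            Document(pmid="100", abstract="SYK with autophagy", year=2010)
        ]
        results = triage(Query(gene=other_gene, max_results=10), docs_syk, bp_lexicon,
                         history=history)
        assert "100" in {r.pmid for r in results}

    def test_status_monotone(self, gene):
        history = HistoryStore()
        query = Query(gene=gene)
        mark_processed(history, query, "100", "completed")
        with pytest.raises(ValueError, match="regression"):
            mark_processed(history, query, "100", "partial")

    def test_log_replay_reconstructs_state(self, gene, tmp_path):
        history = HistoryStore()
        query = Query(gene=gene)
        for pmid, status in (("1", "partial"), ("2", "completed"), ("1", "completed")):
            mark_processed(history, query, pmid, status)
        replayed = HistoryStore.replay(history.log)
        assert replayed.processed == history.processed
        path = tmp_path / "history.jsonl"
        history.save(path)
        assert HistoryStore.load(path).processed == history.processed
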