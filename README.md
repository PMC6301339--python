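# litriage

A desk-scale curation-support toolkit for biological database annotation.
Given a gene and an annotation axis — GO biological process (**BP**) or
disease (**D**) — it ranks MEDLINE-style abstracts for curation, extracts
ontology concepts by dictionary matching with exact character offsets,
turns them into reviewable annotation triplets (*subject protein* —
*relation* — *concept object*, plus an ECO evidence code), and evaluates
the whole pipeline with the standard metrics of dual-curator studies.

It is written for biocurators and text-mining researchers who want a
transparent, fully reproducible reference implementation of this workflow:
every scoring formula is a few lines of inspectable code, every pipeline
stage is byte-deterministic under a fixed seed, and a synthetic-data module
generates complete studies with planted ground truth.

## The model

**Triage.** For a query (gene *g*, axis *a*) the candidates are abstracts
mentioning *g* (after keyword/date/history filtering). Each candidate *d*
gets three component scores, min-max normalized across the candidate set
and combined linearly with configurable weights (default ⅓ each):

- Okapi BM25 of the query terms, with smoothed idf
  `idf(t) = ln(1 + (N − df_t + 0.5)/(df_t + 0.5))`, k1 = 1.2, b = 0.75;
- concept range: distinct axis concepts in *d* over the candidate maximum;
- concept TF-IDF: `Σ_c tf(c,d) · ln(N / df_c)` over matched concepts.

Ties break by year then PMID (descending), making the ranking total.

**Concept extraction.** Dictionary matching over NFKC-casefolded
alphanumeric tokens (so `T-cell activation` ≡ `T cell activation`), with
overlaps resolved longest-span-first then leftmost; ambiguous surface forms
yield one flagged mention per candidate id.

**Annotation ranking.** Candidates appear in text order (*linear view*) or
re-ranked by `tf(c) · ln((N_bg+1)/(df_bg(c)+1))` (*ranked view*), where tf
counts retrieved abstracts mentioning *c* and df_bg comes from a large
background sample — vague ubiquitous terms sink. A blacklist of
always-rejected concepts is filtered out before proposal. Reviews follow
accept / modify (same ontology branch only) / reject semantics; editing the
relation or evidence code alone still counts as accepted.

**Evaluation.** Triage inter-annotator agreement, concept precision from
accepted/modified/rejected counts, recall and concept agreement under
per-abstract *semantic class* equivalence, precision-at-rank (P0, P@5 with
TREC fixed-denominator convention), relative gains, and per-term rejection
tables. Integer percentages are round-half-up throughout.

## Worked example

Generate a synthetic study (30-concept ontology, 20 relevant + 80 decoy
abstracts with planted gene and concept mentions, simulated dual-curator
judgments), then triage and annotate:

```bash
litriage synth --out fx --seed 3
litriage triage SYK1A BP --corpus fx/corpus.jsonl --obo fx/ontology.obo \
    --genes fx/genes.tsv --max 5
```

```
rank  pmid      year  title                                  bm25      range     tfidf      final     status
1     80000010  2020  Important suggest observed increased.  2.038867  1.000000  16.223456  0.928227  not_done
2     80000016  2006  Moreover showed also however.          1.933528  1.000000  15.935774  0.903337  not_done
3     80000012  2014  Found important data results.          2.198573  0.750000  12.429216  0.795712  not_done
4     80000013  2019  Thus experiments however overall.      2.242487  0.750000  10.557414  0.765165  not_done
5     80000014  2005  After using study patients.            2.198573  0.750000  8.254829   0.709943  not_done
```

All five top-ranked abstracts are planted-relevant ones: they mention the
gene *and* several axis concepts, so the range and TF-IDF components lift
them above gene-only decoys. `final` is the weighted combination of the
min-max-normalized components; `range 1.0` marks the concept-richest
candidates.

```bash
litriage annotate --pmid 80000010 --gene SYK1A --axis BP \
    --corpus fx/corpus.jsonl --obo fx/ontology.obo --genes fx/genes.tsv \
    --blacklist fx/blacklist_bp.txt --view ranked --background-df fx/background_df.tsv
```

```
subject    relation        object_id   object_label       eco          pmid      section   sentence_index  start  end  rank_score  status
NX_S00001  is involved in  GO:9000008  cytokine stress    ECO:0000305  80000010  abstract  1               136    151  4.343805    pending
NX_S00001  is involved in  GO:9000025  transport repair   ECO:0000305  80000010  abstract  1               159    175  3.507557    pending
NX_S00001  is involved in  GO:9000014  assembly adhesion  ECO:0000305  80000010  abstract  1               90     107  2.632089    pending
```

Each row is one pending annotation triplet with its evidence location
(sentence index and character span in the abstract); `rank_score` is the
TF-IDF importance — rarer-in-background concepts score higher — and
blacklisted vague terms have already been filtered out. A curator (or the
library's `annot_rank.review`) then accepts, modifies or rejects each row.

Evaluation against the simulated curators:

```bash
litriage eval --judgments-a fx/judgments_a.tsv --judgments-b fx/judgments_b.tsv \
    --classmap fx/classmap.tsv
```

reports the triage contingency (counts and percentages of both-accept /
both-reject / split decisions) and the concept-level agreement (mean
class-Jaccard and the share of abstracts with at least one common class).

Everything is also available as a library (`litriage.triage.triage`,
`litriage.ner.extract_mentions`, `litriage.evaluate.*`, …); the CLI is a
thin wrapper.

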