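# Methods

## Problem setting

Curated protein databases annotate each protein with controlled-vocabulary
statements — here, GO biological-process terms (the *BP axis*) and disease
terms (the *D axis*). Curators face two bottlenecks: deciding *which* papers
to read for a given gene (triage), and converting the text into annotation
triplets *subject protein — relation — concept object* with an ECO evidence
code. `litriage` implements a desk-scale version of a curation-support
pipeline for both tasks, plus the full evaluation battery used to judge such
pipelines against dual-curator annotation.

## Vocabulary and matching

Concepts come from an OBO ontology (BP) or a TSV terminology (D). All
synonym scopes are indexed equally: published rejection tables show that
broad synonyms ("Cancer" for "Malignant neoplasm", "TCR" for a DNA-repair
process) are exactly the surface forms that matter in practice, for better
or worse. The surface index maps *normalized token sequences* to concept
ids. Normalization is NFKC compatibility form plus case folding; tokens are
alphanumeric runs, and every punctuation character — including hyphens and
en-dashes — separates tokens. Hence "T-cell activation" ≡ "T cell
activation" and "Peutz–Jeghers" ≡ "Peutz-Jeghers". Greek letters survive as
token characters and are not transliterated. No stemming is applied by
default: single-token umbrella words ("formation", "growth") already
over-match; stemming would only make that worse.

The matcher enumerates all dictionary hits over a section's token stream
and resolves overlaps by **longer span first, then leftmost**. Longer
surface forms are usually the more specific class ("regulation of cell
cycle" beats "cell cycle"), mirroring the curation rule of preferring child
terms over parents. An ambiguous surface form (one string, several ids)
emits one mention per id, all flagged `ambiguous`, at identical offsets —
ambiguity is surfaced for the curator, never resolved algorithmically,
which is also why the gene lexicon is matched by plain dictionary lookup
with no gene-normalization heuristics. Character offsets are 0-based,
half-open, and always index the original (un-normalized) section text so
the evidence sentence can be highlighted. Title and abstract are addressed
as separate sections because curation guidelines treat title statements
differently; title mentions do count toward candidates by default
(`include_title=False` turns them off).

Sentence boundaries split on `.`, `!`, `?` followed by whitespace and an
uppercase letter or digit; a short abbreviation list ("e.g.", "i.e.",
"et al.", "vs.", "Fig.", …) suppresses false splits. Spans are trimmed and
cover all non-whitespace text.

Obsolete ontology terms are loaded (so old gold files still resolve) but
never matched. Blacklisting flags a concept without deleting it: the
blacklist is applied to annotation candidates only, *after* extraction, so
the evaluation can still count how often blacklisted terms would have been
proposed.

## Triage model

For a query (gene, axis) the candidate set is: documents with at least one
gene mention, inside the optional year window, containing no excluded
keyword, not explicitly excluded, and not already processed for the same
query key (gene accession + axis; keyword options do not change the key).
Three per-document components are computed:

* **BM25** of the query terms (gene symbol + synonyms + boost keywords),

  `score(d) = Σ_t idf(t) · f(t,d)(k1+1) / (f(t,d) + k1(1 − b + b·|d|/avgdl))`

  with the +1-smoothed Robertson idf `idf(t) = ln(1 + (N − df_t + 0.5) /
  (df_t + 0.5))`, which stays positive for df > N/2 and on single-document
  corpora. Defaults k1 = 1.2, b = 0.75 (the standard tuned values).
* **Concept range** — the number of distinct axis concepts found by the
  matcher, divided by the maximum over the candidate set (0 if nobody has
  any concept).
* **Concept TF-IDF** — `Σ_c tf(c,d) · ln(N / concept_df(c))` over distinct
  axis concepts, with mention-level tf and document-level df from the same
  corpus.

Each component is min-max normalized to [0, 1] across the candidate set
(constant components map to zero — they carry no ranking information), and
combined linearly. The production system this emulates never published its
weights, so the defaults are equal thirds, overridable per axis. Min-max
was chosen over z-scores because the components live on incomparable scales
and candidate sets are small. Ties break by year descending then PMID
descending: score ties are a real phenomenon (they caused two extra
abstracts to be annotated in the benchmark study), so the ordering is
deliberately total. The processed-publication history is an append-only log
(JSONL on disk); replaying the log reconstructs the state, and annotation
statuses only move forward (not_done → partial → completed).

## Annotation candidates and re-ranking

Each distinct non-gene concept in a document with a gene mention becomes
one pending candidate triplet, with provenance (sentence index, character
span) from its first mention. Default relations are "is involved in" (BP)
and "is associated with" (D), default evidence code ECO:0000305 (curator
inference); all are editable and none of these edits changes the review
action. The *linear view* orders candidates by text position. The *ranked
view* re-ranks by

`rank_score(c) = tf(c) · ln((N_bg + 1) / (df_bg(c) + 1))`

where tf counts the retrieved abstracts mentioning c (important concepts
recur across the retrieved set) and the background df comes from a large
document sample, so ubiquitous vague terms get an idf near zero and sink.
Document-level tf was chosen over mention-level because the recurrence
signal is across abstracts; +1 smoothing keeps background-unseen concepts
rankable (maximal idf, with a warning). Both axes use this ranker; the
module exposes it behind a plain function so a learned ranker can be
substituted.

Review semantics: *accept* keeps the concept (relation/ECO edits allowed);
*modify* requires a replacement concept in the same ontology branch,
operationalized as sharing at least one non-root is_a ancestor (a flat
terminology with no hierarchy imposes no constraint); *reject* discards the
proposal but keeps the record for the counts.

## Evaluation metrics

* **Triage agreement**: both-accept / both-reject / split contingency over
  a shared pmid set, with round-half-up integer percentages.
* **Concept precision**: (accepted + modified) / total proposals. The
  bundled BP benchmark row sums its actions to 3173 against a printed total
  of 3175; the printed total is kept as the denominator and the mismatch is
  reported as a warning, not silently repaired.
* **Semantic classes**: near-equivalent concepts are grouped per abstract
  by a manually built class map (an input file, never computed — ontology
  hierarchy distance is explicitly a bad proxy, since terms describing one
  experiment can sit in unrelated branches, e.g. "S phase" / "DNA
  replication" / "regulation of cell cycle"). Recall and concept-level
  agreement operate on classes, never raw ids.
* **Concept recall**: gold = classes chosen by both curators (strict) or by
  either (lenient), pooled over abstracts at class-occurrence level
  (micro-average); a gold class counts as recalled if the system proposed
  any concept of that class.
* **Concept IAA**: per abstract, |classes(A) ∩ classes(B)| / |classes(A) ∪
  classes(B)|, reported as the mean plus the fraction of abstracts with at
  least one common class; abstracts where neither curator annotated
  anything are excluded (one aggregated warning).
* **Precision at rank**: P0 ≡ P@1; P@k uses a fixed denominator k even when
  fewer candidates exist (TREC_EVAL convention). Relative gain is the
  round-half-up percentage change over a positive baseline.
* **Rejection tables**: per-concept accepted/modified/rejected counts and
  percentages, thresholded on a minimum proposal count (default 30), with
  always-rejected concepts flagged as blacklist candidates.

Round-half-up (`floor(x + 0.5)`) is used for every integer percentage; it
reproduces all derivable benchmark cells (162/242 → 67, 699/3175 → 22,
2061/3175 → 65, 42/45 → 93, …). The disease-axis triage column of the
bundled benchmark is internally inconsistent in its published form (counts
152/48/42 of 242 give 63/20/17 and 83% agreement; the published labels say
63/17/20 and the prose says 80%); this package computes from the counts and
leaves the discrepancy documented rather than patched.

## Synthetic data generator

The generator emulates the *statistical* structure of the benchmark study,
not natural language — the matcher is dictionary-based, so linguistic
realism adds nothing to correctness testing. Defaults are the study
conditions: 20 relevant abstracts and 80 decoys per query, 2–4 planted
concepts per relevant abstract, synonym surface forms with probability 0.3,
curator accept probability 0.8, per-curator concept recall 0.9, triage
agreement 0.8, a 30-term vocabulary with Zipf-exponent 1.1 concept
popularity, and a background sample of N = 1000 for the re-ranker.

Construction guarantees worth knowing:

* Concept-label words and filler words come from disjoint pools, and
  planted surfaces are separated by at least one filler word, so every
  planted (pmid, concept) pair is recoverable by the matcher — corpus
  recall is 100% *by construction*, which is what makes the planted-
  relevance and blacklist properties sharp.
* The mini-ontology is a uniformly random rooted is_a tree with one
  deliberately shared (ambiguous) synonym and a configurable number of
  vague single-word concepts that seed the blacklist and get df = N in the
  background table.
* Curator coupling: a shared latent triage decision is flipped
  independently per curator with probability e = (1 − √(2a − 1))/2, so
  expected agreement is exactly the configured a (requires a ≥ 0.5). This
  is the simplest mechanism with a closed-form agreement target.
* Everything is driven by `numpy.random.default_rng([seed, stream])` with a
  fixed stream id per generator, so outputs are byte-identical under a
  fixed seed.

What passing tests on synthetic data do **not** show: robustness to real
linguistic variation (inflection, coordination, anaphora), realistic
ambiguity rates, or the benchmark's absolute corpus-dependent performance
numbers (absolute P0, recall percentages, full rejection-table counts),
which depend on MEDLINE-scale corpora and the curators' complete judgment
data. Those numbers serve as formula references only; the arithmetic that
derives percentages, ratios and gains from them is what the package
reproduces exactly.

## Problem sizes and numerical choices

The test suite and the acceptance script run the triage study at 100
documents (20 relevant / 80 decoys) and the curator-recovery study at 2000
documents (1200 relevant / 800 decoys) — large enough that the binomial
noise on an 80% agreement target sits within ±3 points, small enough to run
in seconds. Oracle-equivalence checks sample 400 random BM25 corpora (≤4
docs × ≤6 tokens) and 300 random matcher fixtures (≤20 tokens, ≤10
dictionary entries) per run, with exact (1e-12) and exact-match tolerances
respectively. Degenerate inputs are contracts, not accidents: empty query →
score 0 with a warning; empty candidate set → empty result with exit 0;
zero-denominator percentages → errors; documents lacking a year are
excluded only when a date bound is actually set.

## Known limitations

* No inverted index: scorers are in-memory and desk-scale by design.
* Relation extraction is co-occurrence only; the relation field is a
  configurable default, not predicted.
* Abstract-internal discourse structure (introductory vs result sentences)
  is not modeled; only title-vs-abstract sectioning is available.
* The OBO reader supports the subset needed here (id, name, synonyms, is_a,
  obsolete); xrefs, other relationship types and logical definitions are
  ignored, and ontology release versions are configuration metadata, never
  inferred.
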