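"""Synthetic fixtures: mini-ontologies, gene lexicons, abstract corpora with
planted signal, background concept frequencies and simulated dual-curator
judgments.

The generator emulates the statistical structure of a curation study rather
than natural language: relevant abstracts embed a gene surface form and a
handful of concept surface forms (preferred label or synonym) in filler
prose; decoys carry filler only, or the gene only.  Concept choice follows
a Zipf law so a few concepts dominate, as term frequencies do in real
literature.  Filler words are drawn from a pool disjoint from all concept
label words, so every planted surface form is recoverable by the dictionary
matcher by construction.

Curator simulation couples two annotators through a shared latent triage
decision plus independent symmetric noise: with per-curator flip
probability e, observed agreement is (1-e)^2 + e^2, so e is solved in
closed form from the configured agreement target.

All generators are deterministic under a fixed seed (byte-identical
re-runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import Document
from .evaluate import CurationDecision
from .vocab import GeneEntry


@dataclass
class SynthConfig:
    """Study-design knobs for the synthetic generators.

    Defaults mirror a desk-scale usability study: 20 relevant abstracts per
    query among 80 decoys, 2-4 annotatable concepts per relevant abstract,
    curators who accept ~80% of truly relevant abstracts, find ~90% of the
    planted concepts each, and agree on triage 80% of the time.
    """

    seed: int = 0
    n_relevant: int = 20
    n_decoy: int = 80
    concepts_per_doc_min: int = 2
    concepts_per_doc_max: int = 4
    synonym_use_prob: float = 0.3
    curator_accept_prob: float = 0.8
    curator_concept_recall: float = 0.9
    curator_agreement: float = 0.8
    class_merge_prob: float = 0.2
    vocabulary_size: int = 30
    zipf_exponent: float = 1.1
    decoy_gene_prob: float = 0.5
    n_vague: int = 3
    background_n: int = 1000
    year_min: int = 2000
    year_max: int = 2020

    def __post_init__(self) -> None:
        for name in (
            "synonym_use_prob", "curator_accept_prob", "curator_concept_recall",
            "curator_agreement", "class_merge_prob", "decoy_gene_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.vocabulary_size < 3:
            raise ValueError("vocabulary_size must be >= 3")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# Words usable in concept labels; disjoint from the filler pool below.
LABEL_WORDS = [
    "kinase", "membrane", "activation", "autophagy", "mitotic", "replication",
    "apoptotic", "cytokine", "receptor", "transduction", "nuclear", "transport",
    "adhesion", "migration", "oxidative", "stress", "metabolic", "catabolic",
    "vesicle", "fusion", "repair", "damage", "checkpoint", "spindle", "assembly",
    "chromatin", "remodeling", "translation", "splicing", "degradation",
    "ubiquitin", "proteolysis", "secretion", "differentiation", "proliferation",
    "senescence", "glycolysis", "phagocytosis", "chemotaxis", "angiogenesis",
    "inflammation", "fibrosis", "hypoxia", "lysosome", "ribosome", "telomere",
]

# Vague umbrella labels that curators reject essentially always.
VAGUE_LABELS = ["signaling", "regulation", "pathogenesis", "development", "growth"]

# Filler prose pool; no word may appear in any concept label.
FILLER_WORDS = [
    "we", "found", "that", "these", "data", "suggest", "further", "experiments",
    "measured", "levels", "samples", "after", "treatment", "during", "overall",
    "moreover", "however", "thus", "also", "using", "observed", "study",
    "results", "showed", "indicate", "report", "novel", "role", "important",
    "patients", "cohort", "analysis", "confirmed", "increased", "decreased",
]

GENE_SYMBOLS = [
    ("NX_S00001", "SYK1A", ["p72syk"]),
    ("NX_S00002", "ZQ70", ["zeta70"]),
    ("NX_S00003", "KMT9", ["q9lys"]),
]


@dataclass
class VocabBundle:
    """Generated vocabulary artifacts in the exact on-disk formats the
    loaders consume, plus the ids designated as vague (blacklistable)."""

    obo_text: str
    disease_tsv: str
    genes_tsv: str
    bp_ids: list[str]
    d_ids: list[str]
    vague_bp_ids: list[str]
    vague_d_ids: list[str]

    @property
    def bp_blacklist_text(self) -> str:
        return "# always-rejected vague terms\n" + "".join(
            f"{cid}\n" for cid in self.vague_bp_ids
        )

    @property
    def d_blacklist_text(self) -> str:
        return "# always-rejected vague terms\n" + "".join(
            f"{cid}\n" for cid in self.vague_d_ids
        )


def _unique_labels(rng: np.random.Generator, n: int, words: list[str]) -> list[str]:
    """n distinct two-word labels from the word pool."""
    labels: list[str] = []
    seen: set[tuple[str, str]] = set()
    while len(labels) < n:
        pair = tuple(rng.choice(words, size=2, replace=False))
        if pair in seen:
            continue
        seen.add(pair)
        labels.append(" ".join(pair))
    return labels


def make_mini_ontology(config: SynthConfig) -> VocabBundle:
    """Generate a rooted is_a tree (OBO) and a disease terminology (TSV).

    The tree has exactly ``vocabulary_size`` nodes including one root.
    Labels are multi-word; synonyms include a hyphenated variant of the
    label plus reworded alternatives, and exactly one synonym string is
    deliberately shared between two concepts to exercise ambiguity handling.
    The first ``n_vague`` non-root concepts carry single-word vague labels
    and form the blacklist seed.
    """
    rng = config.rng(1)
    n = config.vocabulary_size
    n_vague = min(config.n_vague, len(VAGUE_LABELS), n - 2)

    bp_ids = [f"GO:{9000000 + i}" for i in range(n)]
    labels = ["biological signal cascade"]  # root
    labels += VAGUE_LABELS[:n_vague]
    labels += _unique_labels(rng, n - 1 - n_vague, LABEL_WORDS)

    synonyms: dict[str, list[str]] = {cid: [] for cid in bp_ids}
    for i in range(1 + n_vague, n):
        words = labels[i].split()
        if rng.random() < 0.5:
            synonyms[bp_ids[i]].append("-".join(words))  # hyphen variant
        if rng.random() < 0.5:
            extra = str(rng.choice(LABEL_WORDS))
            synonyms[bp_ids[i]].append(f"{words[0]} {extra} {words[1]}")
    # one deliberately ambiguous synonym shared by two specific concepts
    if n - 1 - n_vague >= 2:
        shared = "pleiotropic effector cascade"
        synonyms[bp_ids[-1]].append(shared)
        synonyms[bp_ids[-2]].append(shared)

    parents = {bp_ids[0]: None}
    for i in range(1, n):
        parents[bp_ids[i]] = bp_ids[int(rng.integers(0, i))]

    stanzas = ["format-version: 1.2\nontology: synthetic-bp\n"]
    for i, cid in enumerate(bp_ids):
        lines = [f"[Term]", f"id: {cid}", f"name: {labels[i]}"]
        for syn in synonyms[cid]:
            lines.append(f'synonym: "{syn}" EXACT []')
        if parents[cid] is not None:
            pidx = bp_ids.index(parents[cid])
            lines.append(f"is_a: {parents[cid]} ! {labels[pidx]}")
        stanzas.append("\n".join(lines) + "\n")
    obo_text = "\n".join(stanzas)

    # disease terminology: same generative scheme, TSV format
    d_ids = [f"C9{i:04d}" for i in range(n)]
    d_labels = ["systemic disorder condition"]
    d_vague = ["malignancy", "lesion", "abnormality", "dysfunction", "syndrome"][:n_vague]
    d_labels += d_vague
    d_labels += [f"{w} disease" for w in _unique_labels(rng, n - 1 - n_vague, LABEL_WORDS)]
    d_parents = [""] + [d_ids[int(rng.integers(0, i))] for i in range(1, n)]
    d_rows = ["id\tpreferred_label\tsynonyms\tparent_ids"]
    for i, cid in enumerate(d_ids):
        syns = []
        if i > n_vague and rng.random() < 0.5:
            syns.append(d_labels[i].replace(" ", "-"))
        d_rows.append(f"{cid}\t{d_labels[i]}\t{'|'.join(syns)}\t{d_parents[i]}")
    disease_tsv = "\n".join(d_rows) + "\n"

    gene_rows = ["accession\tsymbol\tsynonyms"]
    for acc, sym, syns in GENE_SYMBOLS:
        gene_rows.append(f"{acc}\t{sym}\t{'|'.join(syns)}")
    genes_tsv = "\n".join(gene_rows) + "\n"

    return VocabBundle(
        obo_text=obo_text,
        disease_tsv=disease_tsv,
        genes_tsv=genes_tsv,
        bp_ids=bp_ids,
        d_ids=d_ids,
        vague_bp_ids=bp_ids[1 : 1 + n_vague],
        vague_d_ids=d_ids[1 : 1 + n_vague],
    )


@dataclass
class SynthCorpus:
    documents: list[Document]
    gold: list[tuple[str, str]]  # (pmid, concept_id) planted pairs

    @property
    def relevant_pmids(self) -> set[str]:
        return {pmid for pmid, _ in self.gold}

    def gold_by_pmid(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pmid, cid in self.gold:
            out.setdefault(pmid, set()).add(cid)
        return out

    def gold_tsv(self) -> str:
        lines = ["pmid\tconcept_id"]
        lines += [f"{p}\t{c}" for p, c in self.gold]
        return "\n".join(lines) + "\n"


def _filler(rng: np.random.Generator, n_words: int) -> list[str]:
    return [str(w) for w in rng.choice(FILLER_WORDS, size=n_words)]


def _sentence(words: list[str]) -> str:
    text = " ".join(words)
    return text[0].upper() + text[1:] + "."


def make_corpus(config: SynthConfig, lexicon, gene: GeneEntry) -> SynthCorpus:
    """Generate a JSONL-ready corpus with planted relevance signal.

    Relevant documents embed the gene and k planted concept surface forms,
    each separated by filler words; decoys embed filler only or the gene
    only.  The gold list records every planted (pmid, concept) pair, all of
    which the dictionary matcher recovers by construction.
    """
    rng = config.rng(2)
    concepts = [c for c in lexicon.concepts.values() if not c.obsolete]
    weights = np.array(
        [1.0 / (i + 1) ** config.zipf_exponent for i in range(len(concepts))]
    )
    weights /= weights.sum()

    documents: list[Document] = []
    gold: list[tuple[str, str]] = []
    n_total = config.n_relevant + config.n_decoy
    pmids = [str(80000001 + i) for i in range(n_total)]

    for i in range(config.n_relevant):
        pmid = pmids[i]
        k = int(rng.integers(config.concepts_per_doc_min, config.concepts_per_doc_max + 1))
        k = min(k, len(concepts))
        chosen = rng.choice(len(concepts), size=k, replace=False, p=weights)
        gene_surface = gene.symbol if rng.random() < 0.7 or not gene.synonyms else str(
            rng.choice(gene.synonyms)
        )
        words = _filler(rng, 3) + [gene_surface] + _filler(rng, 2)
        for ci in chosen:
            concept = concepts[int(ci)]
            use_syn = concept.synonyms and rng.random() < config.synonym_use_prob
            surface = str(rng.choice(concept.synonyms)) if use_syn else concept.preferred_label
            words += [surface] + _filler(rng, int(rng.integers(1, 4)))
            gold.append((pmid, concept.id))
        abstract = " ".join(
            [_sentence(words[:6]), _sentence(words[6:]) if len(words) > 6 else ""]
        ).strip()
        documents.append(
            Document(
                pmid=pmid,
                title=_sentence(_filler(rng, 4)),
                abstract=abstract,
                year=int(rng.integers(config.year_min, config.year_max + 1)),
            )
        )

    for i in range(config.n_decoy):
        pmid = pmids[config.n_relevant + i]
        words = _filler(rng, int(rng.integers(10, 20)))
        if rng.random() < config.decoy_gene_prob:
            words.insert(int(rng.integers(0, len(words))), gene.symbol)
        documents.append(
            Document(
                pmid=pmid,
                title=_sentence(_filler(rng, 4)),
                abstract=_sentence(words),
                year=int(rng.integers(config.year_min, config.year_max + 1)),
            )
        )

    return SynthCorpus(documents=documents, gold=gold)


def agreement_flip_prob(agreement: float) -> float:
    """Per-curator flip probability e with (1-e)^2 + e^2 = agreement."""
    if not 0.5 <= agreement <= 1.0:
        raise ValueError("agreement target must be in [0.5, 1.0]")
    return 0.5 * (1.0 - math.sqrt(2.0 * agreement - 1.0))


@dataclass
class CuratorSim:
    decisions_a: dict[str, CurationDecision]
    decisions_b: dict[str, CurationDecision]
    classmap: dict[str, dict[str, int]]

    @staticmethod
    def _tsv(decisions: dict[str, CurationDecision]) -> str:
        lines = ["curator_id\tpmid\taxis\trelevant\tconcept_ids"]
        for pmid in sorted(decisions):
            d = decisions[pmid]
            lines.append(
                f"{d.curator_id}\t{d.pmid}\t{d.axis}\t{int(d.relevant)}\t"
                f"{';'.join(sorted(d.concepts))}"
            )
        return "\n".join(lines) + "\n"

    def tsv_a(self) -> str:
        return self._tsv(self.decisions_a)

    def tsv_b(self) -> str:
        return self._tsv(self.decisions_b)

    def classmap_tsv(self) -> str:
        lines = ["pmid\tconcept_id\tclass"]
        for pmid in sorted(self.classmap):
            for cid, cls in sorted(self.classmap[pmid].items()):
                lines.append(f"{pmid}\t{cid}\t{cls}")
        return "\n".join(lines) + "\n"


def simulate_curators(
    config: SynthConfig, corpus: SynthCorpus, axis: str = "BP"
) -> CuratorSim:
    """Simulate two coupled curators over a synthetic corpus.

    A shared latent triage decision (accept a truly relevant abstract with
    ``curator_accept_prob``, always reject a decoy) is flipped independently
    per curator with the closed-form probability that makes expected
    agreement equal ``curator_agreement``.  A curator who accepts a relevant
    abstract then detects each planted concept with
    ``curator_concept_recall``.  The class map gives each planted concept
    its own semantic class, then merges a configurable fraction of adjacent
    class pairs to exercise class-level (rather than id-level) equivalence.
    """
    rng = config.rng(3)
    flip = agreement_flip_prob(config.curator_agreement)
    gold = corpus.gold_by_pmid()

    dec_a: dict[str, CurationDecision] = {}
    dec_b: dict[str, CurationDecision] = {}
    classmap: dict[str, dict[str, int]] = {}

    for doc in corpus.documents:
        pmid = doc.pmid
        planted = sorted(gold.get(pmid, set()))
        latent = bool(planted) and rng.random() < config.curator_accept_prob
        for curator, store in (("A", dec_a), ("B", dec_b)):
            decision = latent if rng.random() >= flip else not latent
            concepts: set[str] = set()
            if decision and planted:
                concepts = {
                    cid for cid in planted if rng.random() < config.curator_concept_recall
                }
            store[pmid] = CurationDecision(
                curator_id=curator,
                pmid=pmid,
                axis=axis,
                relevant=decision,
                concepts=concepts,
            )
        if planted:
            classes = {}
            next_class = 1
            for cid in planted:
                if (
                    next_class > 1
                    and rng.random() < config.class_merge_prob
                ):
                    classes[cid] = next_class - 1  # merge into previous class
                else:
                    classes[cid] = next_class
                    next_class += 1
            classmap[pmid] = classes

    return CuratorSim(decisions_a=dec_a, decisions_b=dec_b, classmap=classmap)


def make_background_df(
    config: SynthConfig, lexicon, vague_ids: list[str] | None = None
) -> tuple[dict[str, int], int]:
    """Background document frequencies emulating a large literature sample.

    Vague concepts get df = N (zero idf after smoothing is impossible, but
    their idf floor ln((N+1)/(N+1)) = 0 ranks them below any specific
    concept); specific concepts get low df.  Deterministic under the seed.
    """
    rng = config.rng(4)
    n = config.background_n
    vague = set(vague_ids if vague_ids is not None else lexicon.blacklist)
    df: dict[str, int] = {}
    for cid in sorted(lexicon.concepts):
        if lexicon.concepts[cid].obsolete:
            continue
        df[cid] = n if cid in vague else int(rng.integers(1, max(2, n // 10)))
    return df, n


def background_df_tsv(df: dict[str, int], n: int) -> str:
    lines = [f"# N={n}", "concept_id\tdf"]
    lines += [f"{cid}\t{df[cid]}" for cid in sorted(df)]
    return "\n".join(lines) + "\n"


def load_background_df(path) -> tuple[dict[str, int], int]:
    """Read a background frequency TSV written by :func:`background_df_tsv`."""
    df: dict[str, int] = {}
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# N="):
                n = int(line[4:])
                continue
            if not line or line.startswith("concept_id"):
                continue
            cid, val = line.split("\t")
            df[cid] = int(val)
    if n <= 0:
        raise ValueError(f"background table {path}: missing '# N=' header")
    return df, n
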