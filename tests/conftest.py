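import pytest
from hypothesis import settings

from litriage import synth, vocab

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

TINY_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological process root

[Term]
id: GO:0007049
name: Cell cycle
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0051726
name: Regulation of cell cycle
is_a: GO:0007049 ! Cell cycle

[Term]
id: GO:0042110
name: T cell activation
synonym: "T-cell activation" EXACT []
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0006914
name: Autophagy
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0006915
name: Apoptotic process
synonym: "apoptosis" EXACT []
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0016310
name: Phosphorylation
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0046777
name: protein autophosphorylation
is_a: GO:0016310 ! Phosphorylation

[Term]
id: GO:0009405
name: Pathogenesis
is_a: GO:0008150 ! biological process root

[Term]
id: GO:0000001
name: retired process
is_obsolete: true
"""

DISEASE_TSV = """id\tpreferred_label\tsynonyms\tparent_ids
C0000\tdisease root\t\t
C3262\tNeoplasm\tTumor\tC0000
C9305\tMalignant neoplasm\tCancer|Tumor\tC3262
C3324\tPeutz–Jeghers syndrome\t\tC0000
"""


@pytest.fixture
def bp_lexicon(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO, encoding="utf-8")
    return vocab.load_obo(path, axis="BP")


@pytest.fixture
def d_lexicon(tmp_path):
    path = tmp_path / "diseases.tsv"
    path.write_text(DISEASE_TSV, encoding="utf-8")
    return vocab.load_tsv_terminology(path, axis="D")


@pytest.fixture
def gene():
    return vocab.GeneEntry("NX_P43403", "ZAP70", ["zeta-chain kinase"])


@pytest.fixture
def synth_setup(tmp_path):
    """Default synthetic study: ontology + 20 relevant / 80 decoy corpus."""
    config = synth.SynthConfig(seed=7)
    bundle = synth.make_mini_ontology(config)
    obo = tmp_path / "synth.obo"
    obo.write_text(bundle.obo_text, encoding="utf-8")
    lexicon = vocab.load_obo(obo, axis="BP")
    acc, sym, syns = synth.GENE_SYMBOLS[0]
    gene = vocab.GeneEntry(acc, sym, list(syns))
    corpus = synth.make_corpus(config, lexicon, gene)
    return config, bundle, lexicon, gene, corpus
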