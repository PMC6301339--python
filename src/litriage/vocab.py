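"""Controlled vocabularies: ontology/terminology loading, surface-form
indexing and the rejected-term blacklist.

Two annotation axes are supported: GO biological process ("BP"), loaded from
OBO, and a disease terminology ("D"), loaded from TSV.  Every concept's
preferred label and synonyms (all synonym scopes alike) are normalized with
the corpus tokenizer and indexed as token sequences; matching is therefore
case-insensitive and punctuation-insensitive, so "Peutz–Jeghers syndrome"
(en-dash) and "Peutz-Jeghers syndrome" (hyphen) share one index key.
Ambiguous surface forms keep every candidate id.  Blacklisting flags a
concept as never-to-be-proposed without removing it from the lexicon.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import obonet
import pandas as pd

from .corpus import normalize_tokens

AXES = ("BP", "D")

SurfaceKey = tuple[str, ...]


def normalize_surface(surface: str) -> SurfaceKey:
    """Normalized token-sequence key for a label or synonym."""
    return tuple(t.surface for t in normalize_tokens(surface))


@dataclass
class Concept:
    """An ontology class with its synonyms and is_a parents."""

    id: str
    preferred_label: str
    synonyms: list[str] = field(default_factory=list)
    axis: str = "BP"
    parent_ids: list[str] = field(default_factory=list)
    obsolete: bool = False

    def surface_forms(self) -> list[str]:
        return [self.preferred_label] + list(self.synonyms)


@dataclass
class GeneEntry:
    """A gene/protein lexicon entry (accession, primary symbol, synonyms)."""

    accession: str
    symbol: str
    synonyms: list[str] = field(default_factory=list)

    def surface_forms(self) -> list[str]:
        return [self.symbol] + list(self.synonyms)


@dataclass
class Lexicon:
    """Axis-specific concept collection with its surface-form index."""

    axis: str
    concepts: dict[str, Concept] = field(default_factory=dict)
    surface_index: dict[SurfaceKey, set[str]] = field(default_factory=dict)
    blacklist: set[str] = field(default_factory=set)

    def add(self, concept: Concept) -> None:
        if concept.id in self.concepts:
            raise ValueError(f"duplicate concept id {concept.id}")
        self.concepts[concept.id] = concept

    def label_of(self, concept_id: str) -> str:
        return self.concepts[concept_id].preferred_label

    def max_key_len(self) -> int:
        return max((len(k) for k in self.surface_index), default=0)

    # --- hierarchy -------------------------------------------------------

    def ancestors(self, concept_id: str) -> set[str]:
        """is_a ancestor closure of ``concept_id``, including itself."""
        closure: set[str] = set()
        stack = [concept_id]
        while stack:
            cid = stack.pop()
            if cid in closure or cid not in self.concepts:
                continue
            closure.add(cid)
            stack.extend(self.concepts[cid].parent_ids)
        return closure

    def roots(self) -> set[str]:
        return {cid for cid, c in self.concepts.items() if not c.parent_ids}

    def has_hierarchy(self) -> bool:
        return any(c.parent_ids for c in self.concepts.values())

    def same_branch(self, a: str, b: str) -> bool:
        """True when ``a`` and ``b`` share at least one non-root is_a ancestor.

        A flat terminology (no parent information anywhere) imposes no branch
        constraint and always returns True.
        """
        if not self.has_hierarchy():
            return True
        shared = (self.ancestors(a) & self.ancestors(b)) - self.roots()
        return bool(shared)

    # --- serialization ---------------------------------------------------

    def to_json(self) -> str:
        """Canonical JSON serialization (used for byte-determinism checks)."""
        payload = {
            "axis": self.axis,
            "concepts": {
                cid: {
                    "preferred_label": c.preferred_label,
                    "synonyms": sorted(c.synonyms),
                    "parent_ids": sorted(c.parent_ids),
                    "obsolete": c.obsolete,
                }
                for cid, c in sorted(self.concepts.items())
            },
            "surface_index": {
                " ".join(k): sorted(v) for k, v in sorted(self.surface_index.items())
            },
            "blacklist": sorted(self.blacklist),
        }
        return json.dumps(payload, sort_keys=True, ensure_ascii=False)


def build_surface_index(lexicon: Lexicon) -> Lexicon:
    """(Re)build the normalized surface-form index in place.

    Obsolete concepts are excluded from matching but stay resolvable by id.
    Idempotent: rebuilding yields an identical index.
    """
    index: dict[SurfaceKey, set[str]] = {}
    for concept in lexicon.concepts.values():
        if concept.obsolete:
            continue
        for surface in concept.surface_forms():
            key = normalize_surface(surface)
            if key:
                index.setdefault(key, set()).add(concept.id)
    lexicon.surface_index = index
    return lexicon


_SYNONYM_RE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"')


def _synonym_text(raw: str) -> str:
    """Quoted synonym text from an OBO synonym line value (any scope)."""
    m = _SYNONYM_RE.match(raw)
    text = m.group(1) if m else raw
    return text.replace('\\"', '"').strip()


def _validate_obo_stanzas(path) -> None:
    """Light pre-scan: every [Term] stanza needs id and name; ids are unique."""
    seen: set[str] = set()
    stanza_id: str | None = None
    stanza_has_name = False
    in_term = False
    stanza_no = 0

    def close() -> None:
        if in_term:
            if stanza_id is None:
                raise ValueError(f"OBO stanza #{stanza_no}: missing id")
            if not stanza_has_name:
                raise ValueError(f"OBO stanza {stanza_id}: missing name")
            if stanza_id in seen:
                raise ValueError(f"duplicate OBO id {stanza_id}")
            seen.add(stanza_id)

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                close()
                in_term = True
                stanza_no += 1
                stanza_id, stanza_has_name = None, False
            elif line.startswith("["):  # [Typedef] etc.
                close()
                in_term = False
            elif in_term and line.startswith("id:"):
                stanza_id = line[3:].strip()
            elif in_term and line.startswith("name:"):
                stanza_has_name = True
    close()


def load_obo(path, axis: str = "BP") -> Lexicon:
    """Load an OBO ontology into a Lexicon with the surface index built.

    All synonym scopes are indexed equally.  Obsolete terms are loaded (so
    gold files referencing them still resolve) but never matched.
    """
    _validate_obo_stanzas(path)
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    lexicon = Lexicon(axis=axis)
    for cid, data in graph.nodes(data=True):
        name = data.get("name")
        if name is None:
            raise ValueError(f"OBO stanza {cid}: missing name")
        synonyms = []
        for raw in data.get("synonym", []):
            text = _synonym_text(raw)
            if normalize_surface(text):
                synonyms.append(text)
        lexicon.add(
            Concept(
                id=cid,
                preferred_label=name,
                synonyms=synonyms,
                axis=axis,
                parent_ids=sorted(data.get("is_a", [])),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            )
        )
    return build_surface_index(lexicon)


REQUIRED_TSV_COLUMNS = ("id", "preferred_label", "synonyms")


def load_tsv_terminology(path, axis: str = "D") -> Lexicon:
    """Load a TSV terminology (id, preferred_label, pipe-separated synonyms,
    optional pipe-separated parent_ids) into a Lexicon with the index built."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"terminology {path}: missing column(s) {', '.join(missing)}")
    lexicon = Lexicon(axis=axis)
    for idx, row in frame.iterrows():
        lineno = int(idx) + 2  # header is line 1
        cid = row["id"].strip()
        if not cid:
            raise ValueError(f"terminology {path} line {lineno}: blank id")
        synonyms = [
            s.strip() for s in row["synonyms"].split("|")
            if s.strip() and normalize_surface(s)
        ]
        parents = []
        if "parent_ids" in frame.columns:
            parents = [p.strip() for p in row["parent_ids"].split("|") if p.strip()]
        lexicon.add(
            Concept(
                id=cid,
                preferred_label=row["preferred_label"].strip(),
                synonyms=synonyms,
                axis=axis,
                parent_ids=parents,
            )
        )
    return build_surface_index(lexicon)


def load_blacklist(path, lexicon: Lexicon) -> Lexicon:
    """Populate ``lexicon.blacklist`` from a one-id-per-line file.

    '#' comments and blank lines are ignored.  Ids absent from the lexicon
    are reported as warnings, never silently dropped and never fatal.
    Blacklisting only flags concepts; the concept set is unchanged.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if entry not in lexicon.concepts:
                warnings.warn(f"blacklist line {lineno}: unknown concept id {entry}")
                continue
            lexicon.blacklist.add(entry)
    return lexicon


def load_gene_tsv(path) -> list[GeneEntry]:
    """Load a gene/protein lexicon TSV (accession, symbol, pipe-separated synonyms)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "symbol"):
        if col not in frame.columns:
            raise ValueError(f"gene lexicon {path}: missing column {col}")
    entries = []
    for _, row in frame.iterrows():
        synonyms = []
        if "synonyms" in frame.columns:
            synonyms = [s.strip() for s in row["synonyms"].split("|") if s.strip()]
        entries.append(GeneEntry(row["accession"].strip(), row["symbol"].strip(), synonyms))
    return entries


def find_gene(entries: list[GeneEntry], name: str) -> GeneEntry | None:
    """Resolve a gene by accession, symbol or synonym (case-insensitive)."""
    wanted = name.casefold()
    for e in entries:
        if e.accession.casefold() == wanted or any(
            s.casefold() == wanted for s in e.surface_forms()
        ):
            return e
    return None
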