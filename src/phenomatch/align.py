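"""Cross-ontology mappings: ingestion, axiom conversion and extraction.

A *mapping* is a typed correspondence between classes from two ID
namespaces — equivalence, subclass or superclass — with an optional
score and a provenance tag.  External lexical mappings (from a
matching system or a curated source) enter the pipeline as TSV, are
converted to equivalence/subclass axioms above a score threshold, and
the reasoned taxonomy over the integrated ontology is mined back into
an alignment of entailed cross-ontology mappings.

A deliberately minimal exact-string matcher is included as a lexical
baseline; the toolkit itself contains no real lexical matching
algorithm and expects production lexical mappings to come from a
dedicated matcher.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    Axiom,
    EquivalentClasses,
    Named,
    OntologySnapshot,
    SubClassOf,
    curie_prefix,
)
from .reasoner import Taxonomy

RELATIONS = ("equiv", "sub", "super")
PROVENANCES = ("reasoned", "lexical", "xref", "baseline", "curated")

#: Default score threshold; mappings must score strictly above it.
DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True, order=True)
class Mapping:
    """A typed cross-ontology correspondence.

    ``source sub target`` means source is a strict subclass of target.
    Equivalence mappings are canonicalized so the lexicographically
    smaller prefix is the source.
    """

    source: str
    target: str
    relation: str
    score: Optional[float] = None
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if curie_prefix(self.source) == curie_prefix(self.target):
            raise ValueError(
                f"mapping within one namespace: {self.source} / {self.target}")
        if self.relation == "equiv" and curie_prefix(self.source) > curie_prefix(self.target):
            src, tgt = self.source, self.target
            object.__setattr__(self, "source", tgt)
            object.__setattr__(self, "target", src)

    def inverse(self) -> "Mapping":
        rel = {"sub": "super", "super": "sub", "equiv": "equiv"}[self.relation]
        return Mapping(self.target, self.source, rel, self.score, self.provenance)


def _canonical(source: str, target: str, relation: str,
               score: Optional[float], provenance: str) -> Mapping:
    if relation == "equiv" and curie_prefix(source) > curie_prefix(target):
        source, target = target, source
    if relation == "super":
        source, target, relation = target, source, "sub"
    return Mapping(source, target, relation, score, provenance)


@dataclass
class Alignment:
    """A set of mappings between two ID namespaces.

    Only ``equiv`` and ``sub`` are materialized; a superclass mapping
    is the inverse view of a subclass one.
    """

    left_prefix: str
    right_prefix: str
    mappings: frozenset

    def __init__(self, left_prefix: str, right_prefix: str,
                 mappings: Iterable[Mapping] = ()):
        self.left_prefix = left_prefix
        self.right_prefix = right_prefix
        self.mappings = frozenset(mappings)

    @property
    def equiv(self) -> set:
        return {m for m in self.mappings if m.relation == "equiv"}

    @property
    def sub(self) -> set:
        return {m for m in self.mappings if m.relation == "sub"}

    def equiv_pairs(self) -> set:
        return {(m.source, m.target) for m in self.equiv}


# ---------------------------------------------------------------------------
# TSV / RDF carriers
# ---------------------------------------------------------------------------

_COLUMNS = ("source", "target", "relation", "score", "provenance")


def load_alignment_tsv(path: str) -> list[Mapping]:
    """Load mappings from a five-column TSV (header required).

    Columns: source, target, relation (equiv|sub|super), score (empty
    for curated/scoreless mappings), provenance.
    """
    from .model import normalize_id
    mappings: list[Mapping] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in _COLUMNS}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            raw_score = parts[idx["score"]].strip()
            if raw_score in ("", "NA", "None"):
                score = None
            else:
                try:
                    score = float(raw_score)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable score {raw_score!r}") from None
            relation = parts[idx["relation"]].strip()
            if relation not in RELATIONS:
                raise ValueError(f"{path}:{lineno}: unknown relation {relation!r}")
            mappings.append(_canonical(
                normalize_id(parts[idx["source"]]),
                normalize_id(parts[idx["target"]]),
                relation, score, parts[idx["provenance"]].strip() or "curated"))
    return mappings


def write_alignment_tsv(mappings: Iterable[Mapping], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for m in sorted(mappings):
            score = "" if m.score is None else f"{m.score:g}"
            fh.write(f"{m.source}\t{m.target}\t{m.relation}\t{score}\t{m.provenance}\n")


def write_alignment_rdf(mappings: Iterable[Mapping], path: str) -> None:
    """Write the Alignment-format RDF dialect used by matching harnesses."""
    rel_symbol = {"equiv": "=", "sub": "&lt;", "super": "&gt;"}
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<rdf:RDF xmlns="http://knowledgeweb.semanticweb.org/heterogeneity/alignment#"',
        '         xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#">',
        "<Alignment>",
        "  <xml>yes</xml>",
        "  <level>0</level>",
        "  <type>??</type>",
    ]
    for m in sorted(mappings):
        measure = 1.0 if m.score is None else m.score
        lines += [
            "  <map><Cell>",
            f'    <entity1 rdf:resource="{m.source}"/>',
            f'    <entity2 rdf:resource="{m.target}"/>',
            f'    <measure rdf:datatype="xsd:float">{measure:g}</measure>',
            f"    <relation>{rel_symbol[m.relation]}</relation>",
            "  </Cell></map>",
        ]
    lines += ["</Alignment>", "</rdf:RDF>", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# Mappings -> axioms
# ---------------------------------------------------------------------------

def mappings_to_axioms(mappings: Iterable[Mapping],
                       threshold: float = DEFAULT_THRESHOLD) -> tuple[list[Axiom], int]:
    """Convert mappings to axioms, filtering on score.

    A scored mapping is kept only if its score is *strictly greater*
    than the threshold; scoreless (curated) mappings always pass.
    Returns (axioms, number filtered out).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    axioms: list[Axiom] = []
    filtered = 0
    for m in mappings:
        if m.score is not None and m.score <= threshold:
            filtered += 1
            continue
        if m.relation == "equiv":
            axioms.append(EquivalentClasses([Named(m.source), Named(m.target)]))
        elif m.relation == "sub":
            axioms.append(SubClassOf(Named(m.source), Named(m.target)))
        else:  # super
            axioms.append(SubClassOf(Named(m.target), Named(m.source)))
    return axioms, filtered


# ---------------------------------------------------------------------------
# Reasoned extraction
# ---------------------------------------------------------------------------

def extract_mappings(taxonomy: Taxonomy, snapshot: OntologySnapshot,
                     left_prefix: str, right_prefix: str,
                     kinds: Iterable[str] = ("equiv", "sub")) -> Alignment:
    """Mine entailed cross-namespace mappings from a classified taxonomy.

    Equivalence mappings are cross-prefix pairs sharing an equivalence
    group; subclass mappings are strictly subsumed cross-prefix pairs.
    Only classes carrying the two requested prefixes participate, so
    minted grouping classes and support-ontology classes never appear
    in the output.
    """
    kinds = set(kinds)
    present = snapshot.prefixes()
    for p in (left_prefix, right_prefix):
        if p not in present:
            raise ValueError(f"prefix {p!r} absent from snapshot")
    wanted = {left_prefix, right_prefix}

    def side(c: str) -> Optional[str]:
        p = curie_prefix(c)
        return p if p in wanted else None

    mappings: set[Mapping] = set()
    if "equiv" in kinds:
        for group in taxonomy.groups:
            lefts = sorted(c for c in group if side(c) == left_prefix)
            rights = sorted(c for c in group if side(c) == right_prefix)
            for a in lefts:
                for b in rights:
                    mappings.add(_canonical(a, b, "equiv", None, "reasoned"))
    if kinds & {"sub", "super"}:
        for c in sorted(taxonomy.classes):
            if side(c) is None:
                continue
            grp = taxonomy.group_of(c)
            for a in taxonomy.ancestors(c):
                if side(a) is None or side(a) == side(c) or a in grp:
                    continue
                mappings.add(Mapping(c, a, "sub", None, "reasoned"))
    return Alignment(left_prefix, right_prefix, mappings)


# ---------------------------------------------------------------------------
# Lexical baseline
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^a-z0-9]+")


def _fold(s: str) -> str:
    return _PUNCT.sub(" ", s.casefold()).strip()


def exact_label_match(a: OntologySnapshot, b: OntologySnapshot) -> list[Mapping]:
    """Exact-string lexical baseline over labels and synonyms.

    Case-folded, punctuation-normalized exact matches only.  A
    label-label match scores 1.0; a match involving a synonym on
    either side scores 0.9.  This is a floor, not a matcher: real
    pipelines should supply externally generated lexical mappings.
    """
    def strings(snap: OntologySnapshot) -> dict:
        table: dict[str, list] = {}
        for c in snap.classes:
            lbl = snap.labels.get(c)
            if lbl:
                table.setdefault(_fold(lbl), []).append((c, True))
            for syn in snap.synonyms.get(c, ()):
                table.setdefault(_fold(syn), []).append((c, False))
        return table

    ta, tb = strings(a), strings(b)
    best: dict[tuple, float] = {}
    for key, left_hits in ta.items():
        if not key or key not in tb:
            continue
        for ca, la in left_hits:
            for cb, lb in tb[key]:
                if curie_prefix(ca) == curie_prefix(cb):
                    continue
                score = 1.0 if (la and lb) else 0.9
                pair = (ca, cb)
                best[pair] = max(best.get(pair, 0.0), score)
    return sorted(_canonical(ca, cb, "equiv", score, "baseline")
                  for (ca, cb), score in best.items())
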