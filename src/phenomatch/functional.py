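"""Reader/writer for a restricted OWL 2 Functional-Style Syntax subset.

Only the constructs needed for the EL phenotype-integration pipeline
are supported: ``SubClassOf``, ``EquivalentClasses``,
``DisjointClasses``, ``ObjectSomeValuesFrom``, ``ObjectIntersectionOf``,
``SubObjectPropertyOf``, ``TransitiveObjectProperty``,
``ReflexiveObjectProperty``, ``Declaration`` and ``AnnotationAssertion``
for labels, exact synonyms and database cross-references.  Anything
else (``ObjectAllValuesFrom``, data properties, GCIs over unsupported
constructors, ...) is skipped and counted, never an error.

Serialization is deterministic: axioms and declarations are emitted in
sorted order, so writing the same snapshot twice produces byte-identical
files and write->parse is a structural fixed point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

from .model import (
    Axiom,
    ClassExpression,
    Conjunction,
    DisjointClasses,
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
    _expr_key,
    conj,
    curie_prefix,
    normalize_id,
)

logger = logging.getLogger(__name__)

LABEL_PROP = "rdfs:label"
SYNONYM_PROPS = {"oboInOwl:hasExactSynonym", "oboInOwl:hasRelatedSynonym"}
XREF_PROP = "oboInOwl:hasDbXref"

_SKIPPABLE = {
    "ObjectAllValuesFrom", "ObjectUnionOf", "ObjectComplementOf",
    "ObjectOneOf", "ObjectHasValue", "ObjectHasSelf", "ObjectMinCardinality",
    "ObjectMaxCardinality", "ObjectExactCardinality", "DataSomeValuesFrom",
    "DataAllValuesFrom", "DataHasValue", "DataPropertyAssertion",
    "ClassAssertion", "ObjectPropertyAssertion", "SubObjectPropertyChain",
    "FunctionalObjectProperty", "InverseObjectProperties",
    "ObjectPropertyDomain", "ObjectPropertyRange", "SymmetricObjectProperty",
    "AsymmetricObjectProperty", "IrreflexiveObjectProperty", "HasKey",
    "DisjointUnion", "EquivalentObjectProperties", "DatatypeDefinition",
    "AnnotationPropertyDomain", "AnnotationPropertyRange",
    "SubAnnotationPropertyOf",
}


class FunctionalSyntaxError(ValueError):
    """Raised on malformed input, with character position context."""


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<iri><[^<>\s]*>)
  | (?P<eq>:=)
  | (?P<name>[^\s()"<>]+)
    """,
    re.VERBOSE,
)


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if m is None:
            raise FunctionalSyntaxError(f"unexpected character {text[i]!r} at position {i}")
        i = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        tokens.append(_Token(kind, m.group(), m.start()))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0
        self.skipped = 0

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise FunctionalSyntaxError("unexpected end of input (unbalanced parentheses?)")
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise FunctionalSyntaxError(
                f"expected {kind} at position {tok.pos}, found {tok.value!r}")
        return tok

    def skip_balanced(self) -> None:
        """Skip a parenthesized group we do not model."""
        self.expect("lparen")
        depth = 1
        while depth:
            tok = self.next()
            if tok.kind == "lparen":
                depth += 1
            elif tok.kind == "rparen":
                depth -= 1

    def entity(self) -> str:
        tok = self.next()
        if tok.kind not in ("name", "iri"):
            raise FunctionalSyntaxError(
                f"expected an identifier at position {tok.pos}, found {tok.value!r}")
        return normalize_id(tok.value.strip("<>"))

    def class_expression(self) -> Optional[ClassExpression]:
        """Parse a class expression; None if it uses an unsupported constructor."""
        tok = self.next()
        if tok.kind in ("name", "iri") and self.peek() is not None and self.peek().kind == "lparen":
            ctor = tok.value
            if ctor == "ObjectSomeValuesFrom":
                self.expect("lparen")
                role = self.entity()
                filler = self.class_expression()
                self.expect("rparen")
                if filler is None:
                    return None
                return Existential(role, filler)
            if ctor == "ObjectIntersectionOf":
                self.expect("lparen")
                operands: list[ClassExpression] = []
                ok = True
                while self.peek() is not None and self.peek().kind != "rparen":
                    op = self.class_expression()
                    if op is None:
                        ok = False
                    else:
                        operands.append(op)
                self.expect("rparen")
                if not ok or len(operands) < 2:
                    return None
                return conj(*operands)
            # unsupported constructor: consume its group
            self.skip_balanced()
            return None
        if tok.kind in ("name", "iri"):
            return Named(normalize_id(tok.value.strip("<>")))
        raise FunctionalSyntaxError(
            f"expected a class expression at position {tok.pos}, found {tok.value!r}")


def parse_owl_functional(path: str) -> OntologySnapshot:
    """Parse a Functional-Style Syntax file into an :class:`OntologySnapshot`.

    Constructs outside the supported subset are skipped; the total skip
    count is logged and stored on the returned snapshot as
    ``snapshot.skipped_axioms``.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    parser = _Parser(_tokenize(text))
    snap = OntologySnapshot()
    declared_roles: set[str] = set()

    def handle_axiom(ctor: str) -> None:
        p = parser
        if ctor == "Declaration":
            p.expect("lparen")
            what = p.next().value
            p.expect("lparen")
            ent = p.entity()
            p.expect("rparen")
            p.expect("rparen")
            if what == "Class":
                snap.add_class(ent)
            elif what == "ObjectProperty":
                declared_roles.add(ent)
                snap.add_role(ent)
            # other declaration kinds carry no information we keep
            return
        if ctor == "SubClassOf":
            p.expect("lparen")
            sub = p.class_expression()
            sup = p.class_expression()
            p.expect("rparen")
            if sub is None or sup is None:
                p.skipped += 1
            else:
                snap.axioms.append(SubClassOf(sub, sup))
            return
        if ctor == "EquivalentClasses":
            p.expect("lparen")
            operands: list[ClassExpression] = []
            ok = True
            while p.peek() is not None and p.peek().kind != "rparen":
                op = p.class_expression()
                if op is None:
                    ok = False
                else:
                    operands.append(op)
            p.expect("rparen")
            if ok and len(operands) >= 2:
                snap.axioms.append(EquivalentClasses(operands))
            else:
                p.skipped += 1
            return
        if ctor == "DisjointClasses":
            p.expect("lparen")
            names: list[str] = []
            ok = True
            while p.peek() is not None and p.peek().kind != "rparen":
                op = p.class_expression()
                if isinstance(op, Named):
                    names.append(op.curie)
                else:
                    ok = False
            p.expect("rparen")
            if ok and len(names) >= 2:
                snap.axioms.append(DisjointClasses(names))
            else:
                p.skipped += 1
            return
        if ctor == "SubObjectPropertyOf":
            p.expect("lparen")
            first = p.peek()
            if first is not None and first.kind == "name" and first.value == "ObjectPropertyChain":
                p.next()
                p.skip_balanced()
                p.entity()
                p.expect("rparen")
                p.skipped += 1
                return
            sub = p.entity()
            sup = p.entity()
            p.expect("rparen")
            snap.add_role(sub, parents=[sup])
            snap.add_role(sup)
            return
        if ctor == "TransitiveObjectProperty":
            p.expect("lparen")
            role = p.entity()
            p.expect("rparen")
            snap.add_role(role, transitive=True)
            return
        if ctor == "ReflexiveObjectProperty":
            p.expect("lparen")
            role = p.entity()
            p.expect("rparen")
            snap.add_role(role, reflexive=True)
            return
        if ctor == "AnnotationAssertion":
            p.expect("lparen")
            prop = p.next().value
            subj_tok = p.next()
            val_tok = p.next()
            # tolerate a language/datatype tail on the literal
            while p.peek() is not None and p.peek().kind != "rparen":
                p.next()
            p.expect("rparen")
            if subj_tok.kind not in ("name", "iri") or val_tok.kind != "string":
                return
            try:
                subj = normalize_id(subj_tok.value.strip("<>"))
            except ValueError:
                return
            value = val_tok.value[1:-1].replace('\\"', '"')
            if prop == LABEL_PROP:
                snap.labels[subj] = value
            elif prop in SYNONYM_PROPS:
                snap.synonyms.setdefault(subj, set()).add(value)
            elif prop == XREF_PROP:
                try:
                    snap.xrefs.setdefault(subj, set()).add(normalize_id(value))
                except ValueError:
                    pass
            return
        if ctor in _SKIPPABLE:
            p.skip_balanced()
            p.skipped += 1
            return
        raise FunctionalSyntaxError(f"unsupported top-level construct {ctor!r}")

    # Prefix(...) header lines, then Ontology( <axioms> )
    while parser.peek() is not None:
        tok = parser.next()
        if tok.kind != "name":
            raise FunctionalSyntaxError(
                f"expected a construct name at position {tok.pos}, found {tok.value!r}")
        if tok.value == "Prefix":
            parser.skip_balanced()
            continue
        if tok.value == "Ontology":
            parser.expect("lparen")
            # optional ontology IRI(s)
            while parser.peek() is not None and parser.peek().kind == "iri":
                parser.next()
            while parser.peek() is not None and parser.peek().kind != "rparen":
                inner = parser.expect("name")
                handle_axiom(inner.value)
            parser.expect("rparen")
            continue
        handle_axiom(tok.value)

    # ensure every referenced entity is registered
    snap.classes |= snap.referenced_curies() - set(snap.roles)
    for ax in snap.axioms:
        from .model import axiom_roles
        for r in axiom_roles(ax):
            if r not in snap.roles:
                snap.add_role(r)
    if parser.skipped:
        logger.warning("skipped %d out-of-subset constructs in %s", parser.skipped, path)
    snap.skipped_axioms = parser.skipped  # type: ignore[attr-defined]
    return snap


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def _render(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return expr.curie
    if isinstance(expr, Existential):
        return f"ObjectSomeValuesFrom({expr.role} {_render(expr.filler)})"
    return "ObjectIntersectionOf(" + " ".join(_render(o) for o in expr.operands) + ")"


def _render_axiom(ax: Axiom) -> str:
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({_render(ax.sub)} {_render(ax.sup)})"
    if isinstance(ax, EquivalentClasses):
        return "EquivalentClasses(" + " ".join(_render(o) for o in ax.operands) + ")"
    return "DisjointClasses(" + " ".join(ax.curies) + ")"


def _quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def write_owl_functional(snapshot: OntologySnapshot, path: str) -> None:
    """Serialize a snapshot deterministically to Functional-Style Syntax."""
    lines: list[str] = []
    all_classes = (snapshot.classes | snapshot.referenced_curies()) - set(snapshot.roles)
    prefixes = sorted({curie_prefix(c) for c in all_classes}
                      | {curie_prefix(r) for r in snapshot.roles})
    for p in prefixes:
        lines.append(f"Prefix({p}:=<http://purl.obolibrary.org/obo/{p}_>)")
    lines.append("Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)")
    lines.append("Prefix(oboInOwl:=<http://www.geneontology.org/formats/oboInOwl#>)")
    lines.append("Ontology(")
    for c in sorted(all_classes):
        lines.append(f"Declaration(Class({c}))")
    for r in sorted(snapshot.roles):
        lines.append(f"Declaration(ObjectProperty({r}))")
    for rid in sorted(snapshot.roles):
        role = snapshot.roles[rid]
        for parent in sorted(role.parents):
            lines.append(f"SubObjectPropertyOf({rid} {parent})")
        if role.transitive:
            lines.append(f"TransitiveObjectProperty({rid})")
        if role.reflexive:
            lines.append(f"ReflexiveObjectProperty({rid})")
    for ax in sorted((_render_axiom(a) for a in set(snapshot.axioms))):
        lines.append(ax)
    for c in sorted(snapshot.labels):
        if c in snapshot.classes or c in snapshot.roles:
            lines.append(f"AnnotationAssertion({LABEL_PROP} {c} {_quote(snapshot.labels[c])})")
    for c in sorted(snapshot.synonyms):
        for syn in sorted(snapshot.synonyms[c]):
            lines.append(
                f"AnnotationAssertion(oboInOwl:hasExactSynonym {c} {_quote(syn)})")
    for c in sorted(snapshot.xrefs):
        for x in sorted(snapshot.xrefs[c]):
            lines.append(f"AnnotationAssertion({XREF_PROP} {c} {_quote(x)})")
    lines.append(")")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
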