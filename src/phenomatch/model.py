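"""Core domain model for the EL ontology subset.

The whole toolkit operates on a deliberately small description-logic
fragment: named classes, conjunctions and existential restrictions
(OWL 2 EL without nominals, role chains or concrete domains).  Every
axiom a phenotype-ontology integration pipeline needs — asserted
subclass links, Entity-Quality equivalence definitions, lexical
mapping axioms — is expressible in this algebra, and the saturation
reasoner in :mod:`phenomatch.reasoner` is complete for it.

Expressions are immutable, hashable and canonically normalized on
construction: conjunctions are flattened and sorted, so two
structurally equal expressions always compare (and hash) equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union


# ---------------------------------------------------------------------------
# CURIE normalization
# ---------------------------------------------------------------------------

_OBO_PURL = re.compile(r"^<?https?://purl\.obolibrary\.org/obo/([A-Za-z][\w.-]*?)_([\w.-]+)>?$")
_GENERIC_IRI = re.compile(r"^<?https?://[^\s<>]*[#/]([A-Za-z][\w.-]*?)[_:]([\w.-]+)>?$")
_CURIE = re.compile(r"^([A-Za-z][\w.-]*?)[:_]([\w.-]+)$")


def normalize_id(raw: str) -> str:
    """Normalize a class/role identifier to a canonical ``PREFIX:LOCAL`` CURIE.

    Accepts CURIEs (``HP:0000158``), underscore forms (``Orphanet_155899``)
    and OBO-style PURLs (``http://purl.obolibrary.org/obo/HP_0000158``).
    The prefix is upper-cased; the function is idempotent.

    Raises
    ------
    ValueError
        If the input matches none of the recognized shapes.
    """
    raw = raw.strip()
    for pat in (_OBO_PURL, _GENERIC_IRI, _CURIE):
        m = pat.match(raw)
        if m:
            prefix, local = m.group(1), m.group(2)
            return f"{prefix.upper()}:{local}"
    raise ValueError(f"unrecognizable identifier: {raw!r}")


def curie_prefix(curie: str) -> str:
    """Return the prefix part of a normalized CURIE."""
    return curie.split(":", 1)[0]


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Named:
    """A named class, referenced by normalized CURIE."""

    curie: str

    def __str__(self) -> str:
        return self.curie


@dataclass(frozen=True, order=True)
class Existential:
    """Existential restriction ``role some filler``."""

    role: str
    filler: "ClassExpression"

    def __str__(self) -> str:
        return f"({self.role} some {self.filler})"


@dataclass(frozen=True, order=True)
class Conjunction:
    """An order-normalized, flattened intersection of >= 2 expressions."""

    operands: tuple  # tuple of ClassExpression, sorted, length >= 2

    def __str__(self) -> str:
        return "(" + " and ".join(str(o) for o in self.operands) + ")"


ClassExpression = Union[Named, Existential, Conjunction]

_SORT_RANK = {Named: 0, Existential: 1, Conjunction: 2}


def _expr_key(e: ClassExpression):
    if isinstance(e, Named):
        return (0, e.curie)
    if isinstance(e, Existential):
        return (1, e.role, _expr_key(e.filler))
    return (2, tuple(_expr_key(o) for o in e.operands))


def conj(*operands: ClassExpression) -> ClassExpression:
    """Build a normalized conjunction: flattened, deduplicated, sorted.

    A single distinct operand collapses to that operand.
    """
    flat: list[ClassExpression] = []
    for op in operands:
        if isinstance(op, Conjunction):
            flat.extend(op.operands)
        else:
            flat.append(op)
    uniq = sorted(set(flat), key=_expr_key)
    if not uniq:
        raise ValueError("conjunction needs at least one operand")
    if len(uniq) == 1:
        return uniq[0]
    return Conjunction(tuple(uniq))


def some(role: str, filler: ClassExpression) -> Existential:
    return Existential(role, filler)


def named_curies(expr: ClassExpression) -> set[str]:
    """All class CURIEs referenced anywhere inside *expr*."""
    if isinstance(expr, Named):
        return {expr.curie}
    if isinstance(expr, Existential):
        return named_curies(expr.filler)
    out: set[str] = set()
    for op in expr.operands:
        out |= named_curies(op)
    return out


def roles_used(expr: ClassExpression) -> set[str]:
    if isinstance(expr, Named):
        return set()
    if isinstance(expr, Existential):
        return {expr.role} | roles_used(expr.filler)
    out: set[str] = set()
    for op in expr.operands:
        out |= roles_used(op)
    return out


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression

    def __str__(self) -> str:
        return f"SubClassOf({self.sub} {self.sup})"


@dataclass(frozen=True)
class EquivalentClasses:
    """Equivalence of >= 2 expressions; operand order is normalized."""

    operands: tuple

    def __init__(self, operands: Iterable[ClassExpression]):
        ops = sorted(set(operands), key=_expr_key)
        if len(ops) < 2:
            raise ValueError("EquivalentClasses needs >= 2 distinct expressions")
        object.__setattr__(self, "operands", tuple(ops))

    def __str__(self) -> str:
        return "EquivalentClasses(" + " ".join(str(o) for o in self.operands) + ")"


@dataclass(frozen=True)
class DisjointClasses:
    """Pairwise disjointness over named classes only."""

    curies: tuple  # tuple of str, sorted

    def __init__(self, curies: Iterable[str]):
        cs = tuple(sorted(set(curies)))
        if len(cs) < 2:
            raise ValueError("DisjointClasses needs >= 2 classes")
        object.__setattr__(self, "curies", cs)


Axiom = Union[SubClassOf, EquivalentClasses, DisjointClasses]


def axiom_curies(axiom: Axiom) -> set[str]:
    if isinstance(axiom, SubClassOf):
        return named_curies(axiom.sub) | named_curies(axiom.sup)
    if isinstance(axiom, EquivalentClasses):
        out: set[str] = set()
        for op in axiom.operands:
            out |= named_curies(op)
        return out
    return set(axiom.curies)


def axiom_roles(axiom: Axiom) -> set[str]:
    if isinstance(axiom, SubClassOf):
        return roles_used(axiom.sub) | roles_used(axiom.sup)
    if isinstance(axiom, EquivalentClasses):
        out: set[str] = set()
        for op in axiom.operands:
            out |= roles_used(op)
        return out
    return set()


# ---------------------------------------------------------------------------
# Roles and snapshots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Role:
    """An object property with the EL-relevant characteristics."""

    id: str
    transitive: bool = False
    reflexive: bool = False
    parents: frozenset = frozenset()


@dataclass
class OntologySnapshot:
    """An in-memory ontology: classes, roles, axioms and annotations.

    ``prefix_of`` is derived (the CURIE prefix of each class) and kept
    explicit because alignment extraction is organized around ID
    namespaces.
    """

    classes: set = field(default_factory=set)
    roles: dict = field(default_factory=dict)          # curie -> Role
    axioms: list = field(default_factory=list)         # list of Axiom
    labels: dict = field(default_factory=dict)         # curie -> str
    synonyms: dict = field(default_factory=dict)       # curie -> set of str
    xrefs: dict = field(default_factory=dict)          # curie -> set of curie

    @property
    def prefix_of(self) -> dict:
        return {c: curie_prefix(c) for c in self.classes}

    def add_class(self, curie: str, label: Optional[str] = None) -> None:
        self.classes.add(curie)
        if label is not None:
            self.labels[curie] = label

    def add_role(self, curie: str, transitive: bool = False,
                 reflexive: bool = False, parents: Iterable[str] = ()) -> None:
        prev = self.roles.get(curie)
        if prev is not None:
            transitive = transitive or prev.transitive
            reflexive = reflexive or prev.reflexive
            parents = set(parents) | set(prev.parents)
        self.roles[curie] = Role(curie, transitive, reflexive, frozenset(parents))

    def referenced_curies(self) -> set[str]:
        out: set[str] = set()
        for ax in self.axioms:
            out |= axiom_curies(ax)
        return out

    def validate(self) -> None:
        """Check the snapshot invariants; raise ValueError on violation."""
        dangling = self.referenced_curies() - self.classes
        if dangling:
            raise ValueError(f"axioms reference undeclared classes: {sorted(dangling)[:5]}")
        missing_roles = {r for ax in self.axioms for r in axiom_roles(ax)} - set(self.roles)
        if missing_roles:
            raise ValueError(f"axioms reference undeclared roles: {sorted(missing_roles)[:5]}")

    def prefixes(self) -> set[str]:
        return {curie_prefix(c) for c in self.classes}

    def copy(self) -> "OntologySnapshot":
        return OntologySnapshot(
            classes=set(self.classes),
            roles=dict(self.roles),
            axioms=list(self.axioms),
            labels=dict(self.labels),
            synonyms={k: set(v) for k, v in self.synonyms.items()},
            xrefs={k: set(v) for k, v in self.xrefs.items()},
        )


def merge_snapshots(snapshots: Sequence[OntologySnapshot]) -> OntologySnapshot:
    """Union of several snapshots; role flags are OR-combined."""
    out = OntologySnapshot()
    for snap in snapshots:
        out.classes |= snap.classes
        for rid, role in snap.roles.items():
            out.add_role(rid, role.transitive, role.reflexive, role.parents)
        out.axioms.extend(snap.axioms)
        for c, lbl in snap.labels.items():
            out.labels.setdefault(c, lbl)
        for c, syns in snap.synonyms.items():
            out.synonyms.setdefault(c, set()).update(syns)
        for c, xs in snap.xrefs.items():
            out.xrefs.setdefault(c, set()).update(xs)
    # deduplicate axioms preserving first-seen order
    seen: set = set()
    uniq: list[Axiom] = []
    for ax in out.axioms:
        if ax not in seen:
            seen.add(ax)
            uniq.append(ax)
    out.axioms = uniq
    return out


def strip_disjointness(snapshot: OntologySnapshot) -> tuple[OntologySnapshot, int]:
    """Remove all DisjointClasses axioms.

    Different conceptualizations across merged anatomy and phenotype
    ontologies routinely clash on disjointness; dropping those axioms
    before classification avoids spurious unsatisfiable classes.

    Returns the stripped snapshot and the number of axioms removed.
    """
    out = snapshot.copy()
    kept = [ax for ax in out.axioms if not isinstance(ax, DisjointClasses)]
    removed = len(out.axioms) - len(kept)
    out.axioms = kept
    return out, removed
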