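"""Completion-rule saturation classifier for the EL subset.

The reasoner computes the full subsumption preorder of an ontology
whose axioms use only conjunction, existential restriction, role
hierarchy, transitive roles and reflexive roles — the fragment in
which all phenotype-integration axioms live.  The procedure is the
classic two-phase one used by EL reasoners such as ELK:

1. **Normalization** — every complex subexpression is assigned a fresh
   atomic name, keyed by its structure, and told axioms are reduced to
   four shapes: ``A ⊑ B``, ``A1 ⊓ … ⊓ An ⊑ B``, ``A ⊑ ∃r.B`` and
   ``∃r.A ⊑ B``.  Structure-keyed naming means two classes that carry
   the same complex definition share its internal name, so their
   equivalence falls out of the told axioms alone.

2. **Saturation** — a worklist fixpoint over the completion rules:
   told subsumption, conjunction firing, existential introduction,
   existential elimination along exactly-matching roles, edge
   propagation into super-roles, transitivity composition, and the
   reflexivity rule ``X ⊑ ∃r.X`` for every class and reflexive role
   (the rule that makes every anatomical entity a part of itself).

The fixpoint is set-based, so the result is independent of
rule-application order.  The saturated preorder is then reduced to a
:class:`Taxonomy`: equivalence groups (mutually subsumed classes) and
the transitive reduction of the subsumption DAG on those groups.
"""

from __future__ import annotations

import logging
from collections import defaultdict, deque
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    ClassExpression,
    Conjunction,
    DisjointClasses,
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
)

logger = logging.getLogger(__name__)


class UnknownClassError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """The saturated subsumption preorder over named classes.

    ``groups`` partitions the classified classes into equivalence
    groups; ``direct_edges`` is the transitive reduction of the
    subsumption DAG on those groups (child group, parent group).
    """

    groups: tuple            # tuple of frozenset of curie, sorted
    direct_edges: frozenset  # frozenset of (child group index, parent group index)
    _anc: dict = field(repr=False, default_factory=dict)   # curie -> frozenset of curie
    _group_of: dict = field(repr=False, default_factory=dict)

    @property
    def classes(self) -> set:
        return set(self._anc)

    def group_of(self, c: str) -> frozenset:
        self._check(c)
        return self.groups[self._group_of[c]]

    def _check(self, c: str) -> None:
        if c not in self._anc:
            raise UnknownClassError(f"class not classified: {c}")

    def subsumes(self, c1: str, c2: str) -> bool:
        """True iff ``c1 ⊑ c2`` in the saturation (reflexively)."""
        self._check(c1)
        self._check(c2)
        return c2 in self._anc[c1]

    def equivalent(self, c1: str, c2: str) -> bool:
        return self.subsumes(c1, c2) and self.subsumes(c2, c1)

    def ancestors(self, c: str) -> frozenset:
        """All classes subsuming *c*, including *c* itself."""
        self._check(c)
        return self._anc[c]

    def descendants(self, c: str) -> frozenset:
        self._check(c)
        if not hasattr(self, "_desc"):
            desc: dict[str, set] = defaultdict(set)
            for x, ancs in self._anc.items():
                for a in ancs:
                    desc[a].add(x)
            self._desc = {k: frozenset(v) for k, v in desc.items()}
        return self._desc.get(c, frozenset({c}))

    def subsumption_pairs(self) -> set:
        """All derived (sub, super) pairs with sub != super."""
        return {(c, a) for c, ancs in self._anc.items() for a in ancs if a != c}

    def write_edge_tsv(self, path: str) -> None:
        """Export direct subsumption edges as a child/parent CURIE table."""
        reps = [min(g) for g in self.groups]
        rows = sorted((reps[child], reps[parent]) for child, parent in self.direct_edges)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child\tparent\n")
            for c, p in rows:
                fh.write(f"{c}\t{p}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class _Normalizer:
    """Reduce told axioms to the four EL normal forms over atoms.

    Atoms are named-class CURIEs plus fresh internal names (``#n``)
    assigned one per distinct complex subexpression.
    """

    def __init__(self) -> None:
        self.fresh: dict[ClassExpression, str] = {}
        self.subs: list[tuple[str, str]] = []                 # A ⊑ B
        self.conjs: list[tuple[tuple, str]] = []              # A1⊓…⊓An ⊑ B
        self.rhs_exists: list[tuple[str, str, str]] = []      # A ⊑ ∃r.B
        self.lhs_exists: list[tuple[str, str, str]] = []      # ∃r.A ⊑ B

    def name(self, expr: ClassExpression) -> str:
        if isinstance(expr, Named):
            return expr.curie
        if expr in self.fresh:
            return self.fresh[expr]
        atom = f"#{len(self.fresh)}"
        self.fresh[expr] = atom
        if isinstance(expr, Existential):
            filler = self.name(expr.filler)
            self.rhs_exists.append((atom, expr.role, filler))
            self.lhs_exists.append((expr.role, filler, atom))
        else:  # Conjunction
            parts = tuple(self.name(op) for op in expr.operands)
            self.conjs.append((parts, atom))
            for p in parts:
                self.subs.append((atom, p))
        return atom

    def add_subclass(self, sub: ClassExpression, sup: ClassExpression) -> None:
        self.subs.append((self.name(sub), self.name(sup)))


def _normalize(snapshot: OntologySnapshot) -> tuple[_Normalizer, set]:
    norm = _Normalizer()
    n_disjoint = 0
    for ax in snapshot.axioms:
        if isinstance(ax, SubClassOf):
            norm.add_subclass(ax.sub, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            first = ax.operands[0]
            for other in ax.operands[1:]:
                norm.add_subclass(first, other)
                norm.add_subclass(other, first)
        elif isinstance(ax, DisjointClasses):
            n_disjoint += 1
        else:
            raise TypeError(f"non-EL axiom: {ax!r}")
    if n_disjoint:
        logger.warning("ignoring %d DisjointClasses axioms during saturation", n_disjoint)
    atoms = set(snapshot.classes) | set(norm.fresh.values())
    for a, b in norm.subs:
        atoms.add(a)
        atoms.add(b)
    for parts, b in norm.conjs:
        atoms.update(parts)
        atoms.add(b)
    for a, _, b in norm.rhs_exists:
        atoms.add(a)
        atoms.add(b)
    return norm, atoms


def _role_closure(snapshot: OntologySnapshot) -> dict:
    """Reflexive-transitive closure of the role hierarchy (r -> super-roles)."""
    sup: dict[str, set] = {r: {r} for r in snapshot.roles}
    changed = True
    while changed:
        changed = False
        for rid, role in snapshot.roles.items():
            for parent in role.parents:
                for s in sup.get(parent, {parent}):
                    if s not in sup[rid]:
                        sup[rid].add(s)
                        changed = True
    return sup


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def _saturate_atoms(snapshot: OntologySnapshot) -> dict:
    """Run the completion-rule fixpoint; return atom -> set of subsumer atoms."""
    norm, atoms = _normalize(snapshot)
    superroles = _role_closure(snapshot)
    transitive = {r for r, role in snapshot.roles.items() if role.transitive}
    reflexive = {r for r, role in snapshot.roles.items() if role.reflexive}

    told_sub: dict[str, list] = defaultdict(list)
    for a, b in norm.subs:
        told_sub[a].append(b)
    conj_by_atom: dict[str, list] = defaultdict(list)
    for parts, b in norm.conjs:
        for p in set(parts):
            conj_by_atom[p].append((parts, b))
    told_exists: dict[str, list] = defaultdict(list)
    for a, r, b in norm.rhs_exists:
        told_exists[a].append((r, b))
    lhs_index: dict[tuple, list] = defaultdict(list)
    for r, a, b in norm.lhs_exists:
        lhs_index[(r, a)].append(b)

    S: dict[str, set] = {x: {x} for x in atoms}
    succ: dict[str, dict] = defaultdict(lambda: defaultdict(set))  # r -> X -> {Y}
    pred: dict[str, dict] = defaultdict(lambda: defaultdict(set))  # r -> Y -> {X}
    preds_of: dict[str, set] = defaultdict(set)                    # Y -> {(r, X)}

    work: deque = deque()

    def add_sub(x: str, a: str) -> None:
        if a not in S[x]:
            S[x].add(a)
            work.append(("S", x, a))

    def add_edge(r: str, x: str, y: str) -> None:
        # edges are closed under the role hierarchy at insertion time
        for s in superroles.get(r, {r}):
            if y not in succ[s][x]:
                succ[s][x].add(y)
                pred[s][y].add(x)
                preds_of[y].add((s, x))
                work.append(("R", s, x, y))

    for x in atoms:
        work.append(("S", x, x))
        for r in reflexive:
            add_edge(r, x, x)

    while work:
        item = work.popleft()
        if item[0] == "S":
            _, x, a = item
            for b in told_sub.get(a, ()):
                add_sub(x, b)
            for parts, b in conj_by_atom.get(a, ()):
                if all(p in S[x] for p in parts):
                    add_sub(x, b)
            for r, b in told_exists.get(a, ()):
                add_edge(r, x, b)
            # existential elimination where x is the filler side
            for r, w in preds_of.get(x, set()).copy():
                for b in lhs_index.get((r, a), ()):
                    add_sub(w, b)
        else:
            _, r, x, y = item
            for a in S[y].copy():
                for b in lhs_index.get((r, a), ()):
                    add_sub(x, b)
            if r in transitive:
                for z in succ[r][y].copy():
                    add_edge(r, x, z)
                for w in pred[r][x].copy():
                    add_edge(r, w, y)
    return S


def saturate(snapshot: OntologySnapshot) -> Taxonomy:
    """Classify a snapshot and return its :class:`Taxonomy`.

    DisjointClasses axioms, if present, are ignored with a warning (the
    pipeline strips them before classification; there is no bottom
    class in this fragment).
    """
    S = _saturate_atoms(snapshot)
    named = set(snapshot.classes)
    anc = {c: frozenset({a for a in S[c] if a in named}) for c in named}
    return _build_taxonomy(anc)


def taxonomy_from_closure(anc: dict) -> Taxonomy:
    """Build a Taxonomy from a precomputed curie -> ancestor-set closure."""
    return _build_taxonomy({c: frozenset(a) | {c} for c, a in anc.items()})


def _build_taxonomy(anc: dict) -> Taxonomy:
    g = nx.DiGraph()
    g.add_nodes_from(anc)
    for c, ancestors in anc.items():
        for a in ancestors:
            if a != c:
                g.add_edge(c, a)
    cond = nx.condensation(g)
    groups_raw = [frozenset(cond.nodes[n]["members"]) for n in cond.nodes]
    order = sorted(range(len(groups_raw)), key=lambda i: min(groups_raw[i]))
    relabel = {old: new for new, old in enumerate(order)}
    groups = tuple(groups_raw[i] for i in order)
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(groups)))
    dag.add_edges_from((relabel[u], relabel[v]) for u, v in cond.edges)
    reduced = nx.transitive_reduction(dag)
    group_of = {c: idx for idx, grp in enumerate(groups) for c in grp}
    return Taxonomy(
        groups=groups,
        direct_edges=frozenset(reduced.edges),
        _anc=anc,
        _group_of=group_of,
    )


def subsumes(taxonomy: Taxonomy, c1: str, c2: str) -> bool:
    return taxonomy.subsumes(c1, c2)


def ancestors(taxonomy: Taxonomy, c: str) -> frozenset:
    return taxonomy.ancestors(c)
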