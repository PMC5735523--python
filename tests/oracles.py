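"""Independent oracles used by the test suite.

``naive_saturate`` is a deliberately dumb EL fixpoint: its own
axiom flattening, no worklist, no indexing — every rule is re-scanned
over everything until nothing changes.  It shares only the axiom
data classes with the package and none of the reasoner code, so
agreement between the two is a meaningful check.

``random_el_snapshot`` generates small seeded EL ontologies with
conjunctions, existentials, role hierarchies and transitive/reflexive
roles for property-based comparison.
"""

from __future__ import annotations

import itertools

import numpy as np

from phenomatch.model import (
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
    conj,
    some,
)


def _flatten(expr, defs, counter):
    """Name an expression with a fresh symbol; record definitional inclusions.

    Returns the atom for *expr*; ``defs`` collects normal-form axioms
    as tuples: ("sub", a, b) / ("conj", parts, b) / ("rhs", a, r, b) /
    ("lhs", r, a, b).
    """
    if isinstance(expr, Named):
        return expr.curie
    key = ("expr", expr)
    if key in counter:
        return counter[key]
    name = f"@{len(counter)}"
    counter[key] = name
    if isinstance(expr, Existential):
        filler = _flatten(expr.filler, defs, counter)
        defs.append(("rhs", name, expr.role, filler))
        defs.append(("lhs", expr.role, filler, name))
    else:
        parts = tuple(_flatten(op, defs, counter) for op in expr.operands)
        defs.append(("conj", parts, name))
        for p in parts:
            defs.append(("sub", name, p))
    return name


def naive_saturate(snapshot: OntologySnapshot) -> dict:
    """Exhaustive unindexed EL fixpoint; returns curie -> named subsumers."""
    defs: list = []
    counter: dict = {}
    for ax in snapshot.axioms:
        if isinstance(ax, SubClassOf):
            defs.append(("sub", _flatten(ax.sub, defs, counter),
                         _flatten(ax.sup, defs, counter)))
        elif isinstance(ax, EquivalentClasses):
            atoms = [_flatten(op, defs, counter) for op in ax.operands]
            for a, b in itertools.permutations(atoms, 2):
                defs.append(("sub", a, b))

    atoms = set(snapshot.classes)
    for d in defs:
        if d[0] == "sub":
            atoms.update(d[1:])
        elif d[0] == "conj":
            atoms.update(d[1])
            atoms.add(d[2])
        else:
            atoms.add(d[1] if d[0] == "rhs" else d[2])
            atoms.add(d[3] if len(d) > 3 else d[2])
    for d in defs:
        if d[0] == "rhs":
            atoms.add(d[3])
        if d[0] == "lhs":
            atoms.add(d[2])

    # super-role closure
    superroles = {r: {r} for r in snapshot.roles}
    changed = True
    while changed:
        changed = False
        for rid, role in snapshot.roles.items():
            for p in role.parents:
                for s in superroles.get(p, {p}):
                    if s not in superroles[rid]:
                        superroles[rid].add(s)
                        changed = True

    S = {x: {x} for x in atoms}
    R = {r: set() for r in snapshot.roles}
    for r, role in snapshot.roles.items():
        if role.reflexive:
            for x in atoms:
                R[r].add((x, x))

    changed = True
    while changed:
        changed = False

        def add_s(x, a):
            nonlocal changed
            if a not in S[x]:
                S[x].add(a)
                changed = True

        def add_r(r, x, y):
            nonlocal changed
            for s in superroles.get(r, {r}):
                if (x, y) not in R.setdefault(s, set()):
                    R[s].add((x, y))
                    changed = True

        for d in defs:
            if d[0] == "sub":
                _, a, b = d
                for x in atoms:
                    if a in S[x]:
                        add_s(x, b)
            elif d[0] == "conj":
                _, parts, b = d
                for x in atoms:
                    if all(p in S[x] for p in parts):
                        add_s(x, b)
            elif d[0] == "rhs":
                _, a, r, b = d
                for x in atoms:
                    if a in S[x]:
                        add_r(r, x, b)
            else:  # lhs: exists r.a => b
                _, r, a, b = d
                for (x, y) in list(R.get(r, ())):
                    if a in S[y]:
                        add_s(x, b)
        for r in list(R):
            for (x, y) in list(R[r]):
                add_r(r, x, y)  # role-hierarchy propagation
        for r in list(R):
            if r in snapshot.roles and snapshot.roles[r].transitive:
                for (x, y) in list(R[r]):
                    for (y2, z) in list(R[r]):
                        if y2 == y:
                            add_r(r, x, z)

    named = set(snapshot.classes)
    return {c: {a for a in S[c] if a in named} for c in named}


# ---------------------------------------------------------------------------
# Random EL ontologies
# ---------------------------------------------------------------------------

def random_el_snapshot(rng: np.random.Generator,
                       max_classes: int = 30, max_axioms: int = 60) -> OntologySnapshot:
    """A small random EL ontology with all supported features."""
    snap = OntologySnapshot()
    n_classes = int(rng.integers(3, max_classes + 1))
    n_roles = int(rng.integers(1, 4))
    classes = [f"T:{i:04d}" for i in range(n_classes)]
    roles = [f"REL:{i:04d}" for i in range(n_roles)]
    for c in classes:
        snap.add_class(c)
    for i, r in enumerate(roles):
        parents = [roles[int(rng.integers(0, i))]] if i > 0 and rng.random() < 0.4 else []
        snap.add_role(r, transitive=bool(rng.random() < 0.4),
                      reflexive=bool(rng.random() < 0.3), parents=parents)

    def rand_expr(depth: int):
        kind = rng.random()
        if depth <= 0 or kind < 0.45:
            return Named(classes[int(rng.integers(0, n_classes))])
        if kind < 0.75:
            return some(roles[int(rng.integers(0, n_roles))], rand_expr(depth - 1))
        ops = [rand_expr(depth - 1) for _ in range(int(rng.integers(2, 4)))]
        return conj(*ops)

    n_axioms = int(rng.integers(2, max_axioms + 1))
    for _ in range(n_axioms):
        if rng.random() < 0.75:
            snap.axioms.append(SubClassOf(rand_expr(2), rand_expr(2)))
        else:
            a, b = rand_expr(1), rand_expr(1)
            if a != b:
                snap.axioms.append(EquivalentClasses([a, b]))
    snap.classes |= snap.referenced_curies()
    return snap
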