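"""Shared fixtures: hand-built desk ontologies and generated studies."""

from __future__ import annotations

import pytest

from phenomatch import (
    EquivalentClasses,
    FixtureSpec,
    Named,
    OntologySnapshot,
    SubClassOf,
    conj,
    generate_all,
    some,
)
from phenomatch.vocab import (
    ABNORMAL,
    HAS_MODIFIER,
    HAS_PART,
    INHERES_IN,
    PART_OF,
    QUALITY_ROOT,
)

TONGUE = "UBERON:0001723"
MOUTH = "UBERON:0000165"
INCREASED_SIZE = "PATO:0000586"
INCREASED_AMOUNT = "PATO:0000470"
COPPER = "CHEBI:28694"
BRAIN = "UBERON:0000955"
SALIVA_SECRETION = "GO:0046541"


def eq_axiom(phenotype: str, quality: str, entity) -> EquivalentClasses:
    """The original quality-first EQ pattern, exactly as asserted in
    species phenotype ontologies (with the abnormal modifier)."""
    entity_expr = Named(entity) if isinstance(entity, str) else entity
    return EquivalentClasses([
        Named(phenotype),
        some(HAS_PART, conj(Named(quality),
                            some(INHERES_IN, entity_expr),
                            some(HAS_MODIFIER, Named(ABNORMAL)))),
    ])


def support_snapshot(*entities: tuple) -> OntologySnapshot:
    """Support ontology with the quality scaffolding plus given
    (curie, label) anatomy/quality entries."""
    snap = OntologySnapshot()
    snap.add_role(PART_OF, transitive=True, reflexive=True)
    snap.add_class(QUALITY_ROOT, "quality")
    snap.add_class(ABNORMAL, "abnormal")
    snap.axioms.append(SubClassOf(Named(ABNORMAL), Named(QUALITY_ROOT)))
    for curie, label in entities:
        snap.add_class(curie, label)
        if curie.startswith("PATO:"):
            snap.axioms.append(SubClassOf(Named(curie), Named(QUALITY_ROOT)))
    return snap


@pytest.fixture
def macroglossia_axiom() -> EquivalentClasses:
    return eq_axiom("HP:0000158", INCREASED_SIZE, TONGUE)


@pytest.fixture
def tongue_support() -> OntologySnapshot:
    snap = support_snapshot((TONGUE, "tongue"), (MOUTH, "mouth"),
                            (INCREASED_SIZE, "increased size"))
    snap.axioms.append(SubClassOf(Named(TONGUE), some(PART_OF, Named(MOUTH))))
    return snap


@pytest.fixture
def macroglossia_snapshot(macroglossia_axiom) -> OntologySnapshot:
    snap = OntologySnapshot()
    snap.add_class("HP:0000158", "Macroglossia")
    snap.axioms.append(macroglossia_axiom)
    for role in (HAS_PART, INHERES_IN, HAS_MODIFIER):
        snap.add_role(role)
    return snap


def copper_definition(cls: str) -> EquivalentClasses:
    """The shared constrained-entity definition for brain copper accumulation."""
    return eq_axiom(cls, INCREASED_AMOUNT,
                    conj(Named(COPPER), some(PART_OF, Named(BRAIN))))


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic two-species study (with the lexical knob on)."""
    spec = FixtureSpec(seed=11, synonym_fraction=0.2)
    return spec, generate_all(spec)


@pytest.fixture(scope="session")
def noise_free_study():
    """Full overlap and coverage, no corpus noise: exact-recovery regime."""
    spec = FixtureSpec(seed=5, eq_coverage=1.0, overlap_fraction=1.0,
                       dropout_rate=0.0, replacement_rate=0.0)
    return spec, generate_all(spec)
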