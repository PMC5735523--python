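"""EQ detection, entity-first rewriting and integrated-ontology building."""

import pytest

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
from phenomatch.rewrite import (
    RewriteConfig,
    RewriteReport,
    build_integrated,
    detect_eq_definition,
    grouping_curie,
    rewrite_phenotype_axiom,
    rewrite_snapshot,
)
from phenomatch.vocab import (
    ABNORMAL,
    HAS_MODIFIER,
    HAS_PART,
    HAS_QUALITY,
    INHERES_IN,
    PART_OF,
    QUALITY_ROOT,
)

from conftest import (
    INCREASED_SIZE,
    SALIVA_SECRETION,
    TONGUE,
    copper_definition,
    eq_axiom,
    support_snapshot,
)


def test_detect_macroglossia(macroglossia_axiom):
    d = detect_eq_definition(macroglossia_axiom)
    assert d is not None
    assert d.phenotype == "HP:0000158"
    assert d.entity == Named(TONGUE)
    assert d.quality == INCREASED_SIZE
    assert d.modifier == ABNORMAL


def test_detect_salivation_quality_root():
    """A physiological abnormality: the quality is the bare quality root
    and the entity is a biological process."""
    config = RewriteConfig()  # GO is an entity prefix by default
    axiom = eq_axiom("HP:0100755", QUALITY_ROOT, SALIVA_SECRETION)
    d = detect_eq_definition(axiom, config)
    assert d is not None
    assert d.phenotype == "HP:0100755"
    assert d.entity == Named(SALIVA_SECRETION)
    assert d.quality == QUALITY_ROOT
    assert d.modifier == ABNORMAL


@pytest.mark.parametrize("axiom", [
    SubClassOf(Named("HP:1"), Named("HP:2")),
    EquivalentClasses([Named("HP:1"), Named("HP:2")]),
    EquivalentClasses([Named("HP:1"), some(PART_OF, Named("UBERON:1"))]),
])
def test_detect_rejects_non_eq(axiom):
    assert detect_eq_definition(axiom) is None


def test_detect_constrained_entity():
    d = detect_eq_definition(copper_definition("HP:0012676"))
    assert d is not None
    assert isinstance(d.entity, Conjunction)


def test_rewrite_drops_modifier(macroglossia_axiom):
    d = detect_eq_definition(macroglossia_axiom)
    res = rewrite_phenotype_axiom(d)
    for op in res.phenotype_axiom.operands:
        assert HAS_MODIFIER not in str(op)
    assert d.modifier == ABNORMAL  # retained as metadata only


def test_grouping_class_shared_across_phenotypes():
    """Two phenotypes on one entity yield 2 phenotype axioms and 1 grouping."""
    snap = OntologySnapshot()
    snap.add_class("HP:0000001")
    snap.add_class("HP:0000002")
    snap.axioms = [eq_axiom("HP:0000001", INCREASED_SIZE, TONGUE),
                   eq_axiom("HP:0000002", QUALITY_ROOT, TONGUE)]
    for r in (HAS_PART, INHERES_IN, HAS_MODIFIER):
        snap.add_role(r)
    report = RewriteReport()
    out = rewrite_snapshot(snap, report=report)
    assert report.n_eq_detected == 2
    assert report.n_phenotype_axioms == 2
    assert report.grouping_classes == {grouping_curie(TONGUE)}
    eqs = [a for a in out.axioms if isinstance(a, EquivalentClasses)]
    assert len(eqs) == 3  # 2 rewritten + 1 shared grouping


def test_rewrite_counts_over_entities():
    """10 EQ classes over 4 entities: 10 phenotype axioms + 4 groupings."""
    entities = [f"UBERON:{i:07d}" for i in range(1, 5)]
    snap = OntologySnapshot()
    for i in range(10):
        c = f"MP:{i:07d}"
        snap.add_class(c)
        snap.axioms.append(eq_axiom(c, INCREASED_SIZE, entities[i % 4]))
    for r in (HAS_PART, INHERES_IN, HAS_MODIFIER):
        snap.add_role(r)
    report = RewriteReport()
    rewrite_snapshot(snap, report=report)
    assert report.n_phenotype_axioms == 10
    assert len(report.grouping_classes) == 4


def test_rewriting_is_idempotent():
    """The rewritten pattern uses has-quality, not inheres-in, so a second
    pass detects nothing."""
    snap = OntologySnapshot()
    snap.add_class("HP:0000158")
    snap.axioms = [eq_axiom("HP:0000158", INCREASED_SIZE, TONGUE)]
    for r in (HAS_PART, INHERES_IN, HAS_MODIFIER):
        snap.add_role(r)
    once = rewrite_snapshot(snap)
    report = RewriteReport()
    twice = rewrite_snapshot(once, report=report)
    assert report.n_eq_detected == 0
    assert sorted(map(str, twice.axioms)) == sorted(map(str, once.axioms))


def test_keep_original_flag(macroglossia_snapshot):
    out = rewrite_snapshot(macroglossia_snapshot,
                           RewriteConfig(keep_original=True))
    assert macroglossia_snapshot.axioms[0] in out.axioms


def test_missing_quality_replaced_by_root(macroglossia_axiom):
    d = detect_eq_definition(macroglossia_axiom)
    res = rewrite_phenotype_axiom(d, known_qualities={QUALITY_ROOT})
    assert QUALITY_ROOT in str(res.phenotype_axiom)
    assert INCREASED_SIZE not in str(res.phenotype_axiom)


def test_build_plain_union_without_eq(tongue_support):
    """Phenotype ontologies with no EQ axioms merge without rewriting."""
    a, b = OntologySnapshot(), OntologySnapshot()
    a.add_class("HP:0000001")
    a.axioms = [SubClassOf(Named("HP:0000001"), Named("HP:0000000"))]
    b.add_class("MP:0000001")
    report = RewriteReport()
    merged = build_integrated([a, b], [tongue_support], [], report=report)
    assert report.n_eq_detected == 0
    assert {"HP:0000001", "MP:0000001"} <= merged.classes
    assert merged.roles[PART_OF].transitive and merged.roles[PART_OF].reflexive


def test_build_rejects_conflicting_declarations(tongue_support):
    a, b = OntologySnapshot(), OntologySnapshot()
    a.add_class("HP:0000001", "first meaning")
    b.add_class("HP:0000001", "second meaning")
    with pytest.raises(ValueError, match="HP:0000001"):
        build_integrated([a, b], [tongue_support])


def test_emitted_axioms_stay_in_el(macroglossia_snapshot, tongue_support):
    """Everything the build emits is expressible in the EL algebra: the
    axiom list contains only SubClassOf/EquivalentClasses over
    Named/Existential/Conjunction (checked structurally)."""
    merged = build_integrated([macroglossia_snapshot], [tongue_support])

    def el_ok(expr):
        if isinstance(expr, Named):
            return True
        if isinstance(expr, Existential):
            return el_ok(expr.filler)
        if isinstance(expr, Conjunction):
            return len(expr.operands) >= 2 and all(map(el_ok, expr.operands))
        return False

    for ax in merged.axioms:
        if isinstance(ax, SubClassOf):
            assert el_ok(ax.sub) and el_ok(ax.sup)
        else:
            assert isinstance(ax, EquivalentClasses)
            assert all(map(el_ok, ax.operands))
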