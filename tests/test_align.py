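"""Mapping ingestion, score-threshold semantics, reasoned extraction."""

import pytest

from phenomatch.align import (
    Alignment,
    Mapping,
    exact_label_match,
    extract_mappings,
    load_alignment_tsv,
    mappings_to_axioms,
    write_alignment_tsv,
)
from phenomatch.model import (
    EquivalentClasses,
    Named,
    OntologySnapshot,
    SubClassOf,
)
from phenomatch.reasoner import saturate


def test_mapping_equiv_canonical_direction():
    m = Mapping("MP:0000001", "HP:0000001", "equiv", 0.8, "lexical")
    assert (m.source, m.target) == ("HP:0000001", "MP:0000001")
    assert Mapping("HP:0000001", "MP:0000001", "equiv", 0.8, "lexical") == m


def test_mapping_rejects_same_prefix():
    with pytest.raises(ValueError):
        Mapping("HP:1", "HP:2", "equiv")


def test_load_alignment_tsv(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("source\ttarget\trelation\tscore\tprovenance\n"
                 "HP:0004432\tDOID:2583\tequiv\t0.95\tlexical\n"
                 "MP:0000001\tHP:0000002\tsub\t\tcurated\n")
    mappings = load_alignment_tsv(str(p))
    assert len(mappings) == 2
    equiv = next(m for m in mappings if m.relation == "equiv")
    assert (equiv.source, equiv.target) == ("DOID:2583", "HP:0004432")  # canonical
    assert equiv.score == 0.95
    sub = next(m for m in mappings if m.relation == "sub")
    assert sub.score is None


def test_load_alignment_tsv_empty(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("source\ttarget\trelation\tscore\tprovenance\n")
    assert load_alignment_tsv(str(p)) == []


def test_load_alignment_tsv_errors(tmp_path):
    p = tmp_path / "missing.tsv"
    p.write_text("source\ttarget\trelation\n")
    with pytest.raises(ValueError, match="score"):
        load_alignment_tsv(str(p))
    p2 = tmp_path / "badscore.tsv"
    p2.write_text("source\ttarget\trelation\tscore\tprovenance\n"
                  "HP:1\tMP:1\tequiv\tnot-a-number\tlexical\n")
    with pytest.raises(ValueError, match=":2"):
        load_alignment_tsv(str(p2))
    p3 = tmp_path / "badrel.tsv"
    p3.write_text("source\ttarget\trelation\tscore\tprovenance\n"
                  "HP:1\tMP:1\tdisjoint\t0.9\tlexical\n")
    with pytest.raises(ValueError, match="disjoint"):
        load_alignment_tsv(str(p3))


def test_alignment_tsv_round_trip(tmp_path):
    mappings = [Mapping("HP:1", "MP:1", "equiv", 0.8, "lexical"),
                Mapping("MP:2", "HP:2", "sub", None, "reasoned")]
    p = tmp_path / "out.tsv"
    write_alignment_tsv(mappings, str(p))
    assert sorted(load_alignment_tsv(str(p))) == sorted(mappings)


def test_threshold_is_strict():
    """A score of exactly 0.7 is excluded; above passes; scoreless passes."""
    mk = lambda s: Mapping("HP:1", "MP:1", "equiv", s, "lexical")
    axioms, filtered = mappings_to_axioms([mk(0.7)], 0.7)
    assert axioms == [] and filtered == 1
    axioms, filtered = mappings_to_axioms([mk(0.71)], 0.7)
    assert len(axioms) == 1 and filtered == 0
    axioms, filtered = mappings_to_axioms([mk(None)], 0.7)
    assert len(axioms) == 1 and filtered == 0


def test_mappings_to_axioms_hand_count():
    mappings = [Mapping("HP:%d" % i, "MP:%d" % i, "equiv", s, "lexical")
                for i, s in enumerate([0.2, 0.5, 0.7, 0.71, 0.9, None, 1.0, 0.69])]
    axioms, filtered = mappings_to_axioms(mappings, 0.7)
    assert len(axioms) == 4 and filtered == 4
    assert all(isinstance(a, EquivalentClasses) for a in axioms)


def test_sub_and_super_mappings_become_subclass_axioms():
    sub = Mapping("HP:1", "MP:1", "sub")
    axioms, _ = mappings_to_axioms([sub])
    assert axioms == [SubClassOf(Named("HP:1"), Named("MP:1"))]


def _two_prefix_snapshot():
    snap = OntologySnapshot()
    for c in ("HP:1", "HP:2", "MP:1", "MP:2", "PHENO:G-X-1"):
        snap.add_class(c)
    snap.axioms = [
        EquivalentClasses([Named("HP:1"), Named("MP:1")]),
        SubClassOf(Named("HP:2"), Named("MP:2")),
        EquivalentClasses([Named("PHENO:G-X-1"), Named("MP:2")]),
    ]
    return snap


def test_extract_equiv_and_sub():
    snap = _two_prefix_snapshot()
    tax = saturate(snap)
    al = extract_mappings(tax, snap, "HP", "MP")
    assert al.equiv_pairs() == {("HP:1", "MP:1")}
    assert {(m.source, m.target) for m in al.sub} == {("HP:2", "MP:2")}
    # grouping/support classes never appear
    assert not any(c.startswith("PHENO:") for m in al.mappings
                   for c in (m.source, m.target))


def test_extract_symmetric_under_prefix_swap():
    snap = _two_prefix_snapshot()
    tax = saturate(snap)
    a = extract_mappings(tax, snap, "HP", "MP")
    b = extract_mappings(tax, snap, "MP", "HP")
    assert a.mappings == b.mappings  # canonical forms coincide


def test_extract_equiv_disjoint_from_sub():
    snap = _two_prefix_snapshot()
    tax = saturate(snap)
    al = extract_mappings(tax, snap, "HP", "MP")
    assert not {(m.source, m.target) for m in al.equiv} & \
        {(m.source, m.target) for m in al.sub}


def test_extract_missing_prefix_errors():
    snap = _two_prefix_snapshot()
    tax = saturate(snap)
    with pytest.raises(ValueError, match="DOID"):
        extract_mappings(tax, snap, "HP", "DOID")


def test_extract_empty_without_cross_links():
    snap = OntologySnapshot()
    for c in ("HP:1", "MP:1"):
        snap.add_class(c)
    tax = saturate(snap)
    al = extract_mappings(tax, snap, "HP", "MP", kinds={"equiv"})
    assert al.mappings == frozenset()


def test_reinjecting_extracted_mappings_is_monotone():
    """Adding extracted equivalences as axioms and re-classifying never
    shrinks the extracted equivalence set."""
    snap = _two_prefix_snapshot()
    tax = saturate(snap)
    first = extract_mappings(tax, snap, "HP", "MP", kinds={"equiv"})
    axioms, _ = mappings_to_axioms(sorted(first.equiv))
    snap.axioms += axioms
    second = extract_mappings(saturate(snap), snap, "HP", "MP", kinds={"equiv"})
    assert first.equiv_pairs() <= second.equiv_pairs()


def test_exact_label_match_shared_synonym():
    """A synonym shared between namespaces yields a 0.9 baseline mapping."""
    a, b = OntologySnapshot(), OntologySnapshot()
    a.add_class("DOID:2583", "agammaglobulinemia")
    a.synonyms["DOID:2583"] = {"hypogammaglobulinemia"}
    b.add_class("MP:0001805", "decreased IgG level")
    b.synonyms["MP:0001805"] = {"Hypogammaglobulinemia"}
    (m,) = exact_label_match(a, b)
    assert (m.source, m.target) == ("DOID:2583", "MP:0001805")
    assert m.score == 0.9 and m.provenance == "baseline"


def test_exact_label_match_label_vs_none():
    a, b = OntologySnapshot(), OntologySnapshot()
    a.add_class("HP:1", "Macroglossia")
    b.add_class("MP:1", "macroglossia!")  # punctuation-insensitive, 1.0
    b.add_class("MP:2", "unrelated label")
    matches = exact_label_match(a, b)
    assert [(m.source, m.target, m.score) for m in matches] == [("HP:1", "MP:1", 1.0)]
    b2 = OntologySnapshot()
    b2.add_class("MP:3", "nothing shared")
    assert exact_label_match(a, b2) == []


def test_exact_label_match_planted_count():
    a, b = OntologySnapshot(), OntologySnapshot()
    for i in range(10):
        a.add_class(f"HP:{i}", f"left term {i}")
        b.add_class(f"MP:{i}", f"right term {i}")
    for i in range(4):  # plant 4 shared labels
        a.labels[f"HP:{i}"] = f"shared term {i}"
        b.labels[f"MP:{i}"] = f"shared term {i}"
    assert len(exact_label_match(a, b)) == 4
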