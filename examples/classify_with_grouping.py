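"""Classify a tiny integrated ontology and show grouping-class inference.

Macroglossia (a tongue phenotype) and an unrelated mouth phenotype are
merged with a mini anatomy in which the tongue is part of the mouth.
After saturation, macroglossia classifies under BOTH grouping classes:
directly under 'tongue abnormality', and under 'mouth abnormality'
because 'part of' is transitive and reflexive.
"""

from phenomatch import (
    Named,
    OntologySnapshot,
    SubClassOf,
    build_integrated,
    conj,
    saturate,
    some,
)
from phenomatch.rewrite import grouping_curie
from phenomatch.vocab import (
    ABNORMAL,
    HAS_MODIFIER,
    HAS_PART,
    INHERES_IN,
    PART_OF,
    QUALITY_ROOT,
)
from phenomatch.model import EquivalentClasses

TONGUE, MOUTH = "UBERON:0001723", "UBERON:0000165"
INCREASED_SIZE = "PATO:0000586"


def eq(phenotype, quality, entity):
    return EquivalentClasses([
        Named(phenotype),
        some(HAS_PART, conj(Named(quality),
                            some(INHERES_IN, Named(entity)),
                            some(HAS_MODIFIER, Named(ABNORMAL)))),
    ])


phenotypes = OntologySnapshot()
phenotypes.add_class("HP:0000158", "Macroglossia")
phenotypes.add_class("HP:0000153", "Abnormality of the mouth")
phenotypes.axioms = [eq("HP:0000158", INCREASED_SIZE, TONGUE),
                     eq("HP:0000153", QUALITY_ROOT, MOUTH)]
for role in (HAS_PART, INHERES_IN, HAS_MODIFIER):
    phenotypes.add_role(role)

anatomy = OntologySnapshot()
for curie, label in [(TONGUE, "tongue"), (MOUTH, "mouth"),
                     (INCREASED_SIZE, "increased size"),
                     (QUALITY_ROOT, "quality"), (ABNORMAL, "abnormal")]:
    anatomy.add_class(curie, label)
anatomy.add_role(PART_OF, transitive=True, reflexive=True)
anatomy.axioms = [
    SubClassOf(Named(TONGUE), some(PART_OF, Named(MOUTH))),
    SubClassOf(Named(INCREASED_SIZE), Named(QUALITY_ROOT)),
    SubClassOf(Named(ABNORMAL), Named(QUALITY_ROOT)),
]

merged = build_integrated([phenotypes], [anatomy])
taxonomy = saturate(merged)

tongue_group, mouth_group = grouping_curie(TONGUE), grouping_curie(MOUTH)
print(f"classes after merge: {len(merged.classes)}; axioms: {len(merged.axioms)}")
for group in (tongue_group, mouth_group):
    verdict = taxonomy.subsumes("HP:0000158", group)
    print(f"macroglossia under {merged.labels[group]!r} ({group}): {verdict}")
print("\nBoth are True: the tongue-first definition plus part-of reasoning")
print("places the phenotype under every anatomical grouping it affects.")
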