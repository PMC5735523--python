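"""Rewrite a quality-first Entity-Quality definition into the
entity-first pattern.

Builds the classic macroglossia definition — 'has part' some
('increased size' and ('inheres in' some tongue) and ('has modifier'
some abnormal)) — detects its EQ decomposition, and prints the two
axioms the rewriter emits: the tongue-first phenotype definition and
the minted 'tongue abnormality' grouping class.
"""

from phenomatch import (
    EquivalentClasses,
    Named,
    conj,
    detect_eq_definition,
    rewrite_phenotype_axiom,
    some,
)
from phenomatch.vocab import ABNORMAL, HAS_MODIFIER, HAS_PART, INHERES_IN

TONGUE = "UBERON:0001723"          # tongue
INCREASED_SIZE = "PATO:0000586"    # increased size

macroglossia = EquivalentClasses([
    Named("HP:0000158"),           # macroglossia
    some(HAS_PART, conj(Named(INCREASED_SIZE),
                        some(INHERES_IN, Named(TONGUE)),
                        some(HAS_MODIFIER, Named(ABNORMAL)))),
])

defn = detect_eq_definition(macroglossia)
print("detected EQ decomposition:")
print(f"  phenotype = {defn.phenotype}  entity = {defn.entity}")
print(f"  quality   = {defn.quality}  modifier = {defn.modifier}")

result = rewrite_phenotype_axiom(defn)
print("\nrewritten phenotype axiom (entity-first, modifier dropped):")
print(f"  {result.phenotype_axiom}")
print(f"\ngrouping class {result.grouping_class}:")
print(f"  {result.grouping_axiom}")
print("\nThe first axiom redefines macroglossia around the tongue; the second")
print("mints a class that will collect every phenotype affecting the tongue")
print("or any of its parts once part-of transitivity/reflexivity apply.")
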