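"""Shared role and class vocabulary.

Standard OBO relation identifiers used by Entity-Quality phenotype
definitions and by the rewritten entity-first axiom pattern.
"""

HAS_PART = "BFO:0000051"
PART_OF = "BFO:0000050"
INHERES_IN = "RO:0000052"
HAS_MODIFIER = "RO:0002573"
HAS_QUALITY = "RO:0000086"

#: Root of the quality ontology ("quality" in PATO).
QUALITY_ROOT = "PATO:0000001"
#: The "abnormal" modifier class.
ABNORMAL = "PATO:0000460"

#: Default prefixes from which EQ entity classes are drawn.
DEFAULT_ENTITY_PREFIXES = frozenset(
    {"UBERON", "GO", "CL", "NBO", "ZFA", "CHEBI", "MPATH"})
#: Default prefix of quality classes.
DEFAULT_QUALITY_PREFIX = "PATO"
#: Prefix under which grouping classes are minted.
DEFAULT_GROUPING_PREFIX = "PHENO"
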