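"""Entity-Quality definition detection and entity-first rewriting.

Species phenotype ontologies define many of their classes with the
Entity-Quality (EQ) pattern::

    P EquivalentTo: 'has part' some (Q and ('inheres in' some E)
                                       [and ('has modifier' some M)])

where E is an anatomical entity or physiological process and Q is a
quality.  Classifying on that pattern groups phenotypes primarily by
quality.  This module rewrites each detected definition into an
entity-first pattern and mints a per-entity grouping class::

    P    EquivalentTo: 'has part' some (E and has-quality some Q)
    G(E) EquivalentTo: 'has part' some (('part of' some E)
                                        and has-quality some Quality)

Together with transitivity and reflexivity of 'part of', every
phenotype affecting E or any of its parts classifies under G(E).  The
modifier conjunct is dropped from the rewritten axiom and retained as
metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import vocab
from .model import (
    Axiom,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
    conj,
    curie_prefix,
    merge_snapshots,
    some,
    strip_disjointness,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RewriteConfig:
    """Knobs of the rewriting pattern.

    ``entity_prefixes`` of ``None`` accepts any non-quality prefix as
    an entity namespace (useful for ad-hoc inputs).
    """

    entity_prefixes: Optional[frozenset] = vocab.DEFAULT_ENTITY_PREFIXES
    quality_prefix: str = vocab.DEFAULT_QUALITY_PREFIX
    quality_root: str = vocab.QUALITY_ROOT
    grouping_prefix: str = vocab.DEFAULT_GROUPING_PREFIX
    keep_original: bool = False
    has_part: str = vocab.HAS_PART
    part_of: str = vocab.PART_OF
    inheres_in: str = vocab.INHERES_IN
    has_modifier: str = vocab.HAS_MODIFIER
    has_quality: str = vocab.HAS_QUALITY


@dataclass(frozen=True)
class EQDefinition:
    """A detected Entity-Quality definition."""

    phenotype: str
    entity: ClassExpression
    quality: str
    modifier: Optional[str] = None


@dataclass(frozen=True)
class RewriteResult:
    phenotype_axiom: Axiom
    grouping_class: Optional[str]
    grouping_axiom: Optional[Axiom]
    source: str


def detect_eq_definition(axiom: Axiom,
                         config: RewriteConfig = RewriteConfig()) -> Optional[EQDefinition]:
    """Match *axiom* against the EQ pattern; return its decomposition or None.

    The pattern is ``EquivalentClasses(P, has-part some (Q and
    (inheres-in some E) [and (has-modifier some M)]))`` up to conjunct
    order, with Q a named quality-prefix class and E any expression
    (possibly a further-constrained conjunction).  Anything else —
    including already-rewritten entity-first definitions, which use
    has-quality instead of inheres-in — yields None.
    """
    if not isinstance(axiom, EquivalentClasses) or len(axiom.operands) != 2:
        return None
    named = [op for op in axiom.operands if isinstance(op, Named)]
    complexes = [op for op in axiom.operands if not isinstance(op, Named)]
    if len(named) != 1 or len(complexes) != 1:
        return None
    phenotype = named[0].curie
    expr = complexes[0]
    if not (isinstance(expr, Existential) and expr.role == config.has_part):
        return None
    filler = expr.filler
    conjuncts: Sequence[ClassExpression]
    if isinstance(filler, Conjunction):
        conjuncts = filler.operands
    else:
        conjuncts = (filler,)

    quality: Optional[str] = None
    entity: Optional[ClassExpression] = None
    modifier: Optional[str] = None
    for c in conjuncts:
        if isinstance(c, Named) and curie_prefix(c.curie) == config.quality_prefix:
            if quality is not None:
                return None
            quality = c.curie
        elif isinstance(c, Existential) and c.role == config.inheres_in:
            if entity is not None:
                return None
            entity = c.filler
        elif (isinstance(c, Existential) and c.role == config.has_modifier
              and isinstance(c.filler, Named)):
            if modifier is not None:
                return None
            modifier = c.filler.curie
        else:
            return None
    if quality is None or entity is None:
        return None
    if config.entity_prefixes is not None:
        primary = primary_entity(entity)
        if primary is None or curie_prefix(primary) not in config.entity_prefixes:
            return None
    return EQDefinition(phenotype, entity, quality, modifier)


def primary_entity(entity: ClassExpression) -> Optional[str]:
    """The named class a grouping class is minted for.

    For a named entity, itself; for a constrained entity (a
    conjunction such as ``'copper atom' and 'part of' some brain``),
    the first named conjunct in canonical order — a declared
    tie-break.  None if the expression has no top-level named conjunct.
    """
    if isinstance(entity, Named):
        return entity.curie
    if isinstance(entity, Conjunction):
        for op in entity.operands:
            if isinstance(op, Named):
                return op.curie
    return None


def grouping_curie(entity_curie: str, config: RewriteConfig = RewriteConfig()) -> str:
    prefix, local = entity_curie.split(":", 1)
    return f"{config.grouping_prefix}:G-{prefix}-{local}"


def rewrite_phenotype_axiom(defn: EQDefinition,
                            config: RewriteConfig = RewriteConfig(),
                            known_qualities: Optional[set] = None) -> RewriteResult:
    """Emit the entity-first phenotype axiom and the grouping-class axiom.

    The grouping class CURIE is a pure function of the entity, so
    phenotypes sharing an entity share one grouping class.  A quality
    missing from the known quality set is replaced by the quality root
    with a warning.
    """
    quality = defn.quality
    if known_qualities is not None and quality not in known_qualities:
        logger.warning("quality %s not found in quality ontology; using root %s",
                       quality, config.quality_root)
        quality = config.quality_root
    phenotype_axiom = EquivalentClasses([
        Named(defn.phenotype),
        some(config.has_part,
             conj(defn.entity, some(config.has_quality, Named(quality)))),
    ])
    primary = primary_entity(defn.entity)
    if primary is None:
        return RewriteResult(phenotype_axiom, None, None, defn.phenotype)
    g = grouping_curie(primary, config)
    grouping_axiom = EquivalentClasses([
        Named(g),
        some(config.has_part,
             conj(some(config.part_of, Named(primary)),
                  some(config.has_quality, Named(config.quality_root)))),
    ])
    return RewriteResult(phenotype_axiom, g, grouping_axiom, defn.phenotype)


@dataclass
class RewriteReport:
    n_axioms_scanned: int = 0
    n_eq_detected: int = 0
    n_phenotype_axioms: int = 0
    grouping_classes: set = field(default_factory=set)
    n_disjointness_stripped: int = 0
    n_mapping_axioms: int = 0


def rewrite_snapshot(snapshot: OntologySnapshot,
                     config: RewriteConfig = RewriteConfig(),
                     known_qualities: Optional[set] = None,
                     report: Optional[RewriteReport] = None,
                     entity_labels: Optional[dict] = None) -> OntologySnapshot:
    """Rewrite every detected EQ definition in a snapshot.

    Detected original axioms are replaced by their rewritten forms
    (kept alongside when ``config.keep_original``); grouping classes
    are minted, deduplicated and labelled ``"<entity label>
    abnormality"`` where the entity label is known.
    """
    if report is None:
        report = RewriteReport()
    out = snapshot.copy()
    new_axioms: list[Axiom] = []
    grouping_axioms: dict[str, Axiom] = {}
    for ax in snapshot.axioms:
        report.n_axioms_scanned += 1
        defn = detect_eq_definition(ax, config)
        if defn is None:
            new_axioms.append(ax)
            continue
        report.n_eq_detected += 1
        res = rewrite_phenotype_axiom(defn, config, known_qualities)
        if config.keep_original:
            new_axioms.append(ax)
        new_axioms.append(res.phenotype_axiom)
        report.n_phenotype_axioms += 1
        if res.grouping_class is not None and res.grouping_class not in grouping_axioms:
            grouping_axioms[res.grouping_class] = res.grouping_axiom
            entity = primary_entity(defn.entity)
            label = (entity_labels or {}).get(entity) or snapshot.labels.get(entity, entity)
            out.labels[res.grouping_class] = f"{label} abnormality"
    for g, gax in grouping_axioms.items():
        out.add_class(g)
        new_axioms.append(gax)
    report.grouping_classes |= set(grouping_axioms)
    out.axioms = new_axioms
    out.classes |= out.referenced_curies()
    for role in (config.has_part, config.has_quality, config.part_of):
        if role not in out.roles:
            out.add_role(role)
    return out


def _label_collisions(snapshots: Sequence[OntologySnapshot]) -> list[str]:
    seen: dict[str, str] = {}
    clashes: list[str] = []
    for snap in snapshots:
        for c, lbl in snap.labels.items():
            if c in seen and seen[c] != lbl:
                clashes.append(c)
            seen.setdefault(c, lbl)
    return clashes


def build_integrated(phenotype_snapshots: Sequence[OntologySnapshot],
                     support_snapshots: Sequence[OntologySnapshot] = (),
                     mapping_axioms: Iterable[Axiom] = (),
                     config: RewriteConfig = RewriteConfig(),
                     report: Optional[RewriteReport] = None) -> OntologySnapshot:
    """Merge phenotype and support ontologies into one integrated snapshot.

    The union contains the phenotype ontologies' named classes and
    asserted axioms with EQ definitions rewritten, the support
    ontologies with disjointness stripped, and any mapping axioms
    (lexical, cross-reference or curated equivalences).  The 'part of'
    role is flagged transitive and reflexive — the rewriting pattern
    depends on both.
    """
    if report is None:
        report = RewriteReport()
    clashes = _label_collisions(phenotype_snapshots)
    if clashes:
        raise ValueError(f"class identifiers declared with conflicting labels in "
                         f"multiple input ontologies: {sorted(clashes)[:10]}")
    known_qualities: set = set()
    stripped_support: list[OntologySnapshot] = []
    for snap in support_snapshots:
        stripped, n = strip_disjointness(snap)
        report.n_disjointness_stripped += n
        stripped_support.append(stripped)
        known_qualities |= {c for c in stripped.classes
                            if curie_prefix(c) == config.quality_prefix}
    if not known_qualities:
        known_qualities = None  # no quality ontology supplied; trust inputs
    support_labels: dict = {}
    for snap in stripped_support:
        support_labels.update(snap.labels)
    rewritten = [rewrite_snapshot(s, config, known_qualities, report,
                                  entity_labels=support_labels)
                 for s in phenotype_snapshots]
    merged = merge_snapshots(rewritten + stripped_support)
    mapping_axioms = list(mapping_axioms)
    report.n_mapping_axioms += len(mapping_axioms)
    merged.axioms.extend(ax for ax in mapping_axioms if ax not in set(merged.axioms))
    merged.classes |= merged.referenced_curies()
    merged.add_role(config.part_of, transitive=True, reflexive=True)
    for role in (config.has_part, config.has_quality, config.inheres_in,
                 config.has_modifier):
        if role not in merged.roles:
            merged.add_role(role)
    if config.quality_root not in merged.classes:
        merged.add_class(config.quality_root, "quality")
    return merged
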