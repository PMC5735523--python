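"""Seeded synthetic fixtures: support ontologies, paired species
phenotype ontologies with a planted ground-truth alignment, and
annotation corpora with planted gene-disease associations.

The generators emulate the structure the integration pipeline is built
for, at desk scale and fully offline:

* an anatomy ontology — a rooted is_a tree whose every child is also
  'part of' its parent, plus occasional extra part-of edges (organs
  spanning systems);
* a quality tree under a quality root, with an "abnormal" modifier
  class;
* two species phenotype ontologies (prefixes SPA and SPB) whose
  classes are EQ-defined over the shared anatomy and qualities.  A
  controlled fraction of (entity, quality) templates is shared
  verbatim between the species: those class pairs are the planted
  alignment that axiomatic reasoning should recover.  Species labels
  share no strings by default; a planted-synonym fraction marks
  additional cross-species pairs recoverable only lexically;
* gene and disease corpora: genes annotate species-A classes, each
  disease copies its causal gene's annotations translated to
  species B, degraded by dropout and random replacement.

Everything is a pure function of the :class:`FixtureSpec`; the same
spec regenerates byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Set, Tuple

import numpy as np

from .align import Alignment, Mapping
from .model import (
    EquivalentClasses,
    Existential,
    Named,
    OntologySnapshot,
    SubClassOf,
    conj,
    some,
)
from .rewrite import RewriteConfig
from .semsim import AnnotationCorpus

ANATOMY_PREFIX = "ANAT"
QUALITY_PREFIX = "QUAL"
SPECIES_A = "SPA"
SPECIES_B = "SPB"
QUALITY_ROOT = "QUAL:0000000"
ABNORMAL = "QUAL:0900000"
GROUPING_PREFIX = "GRP"


def fixture_rewrite_config(**overrides) -> RewriteConfig:
    """Rewrite configuration matching the synthetic vocabulary."""
    base = RewriteConfig(
        entity_prefixes=frozenset({ANATOMY_PREFIX}),
        quality_prefix=QUALITY_PREFIX,
        quality_root=QUALITY_ROOT,
        grouping_prefix=GROUPING_PREFIX,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class FixtureSpec:
    """All generation parameters; generation is a pure function of this.

    Defaults model a small two-species study: a 40-class anatomy
    (depth 3, branching 3), 8 qualities, 40 phenotype classes per
    species of which half carry EQ definitions (mirroring the roughly
    half of real species phenotype ontologies that are formally
    constrained), 30% sharing templates across species, and corpora of
    50 genes / 30 diseases with 8 annotations each, 20% dropout and
    10% random replacement.
    """

    anatomy_depth: int = 3
    anatomy_branching: int = 3
    extra_part_of_prob: float = 0.1
    n_qualities: int = 8
    n_phenotypes_per_species: int = 40
    eq_coverage: float = 0.5
    overlap_fraction: float = 0.3
    synonym_fraction: float = 0.0
    n_genes: int = 50
    n_diseases: int = 30
    annotations_per_entity: int = 8
    dropout_rate: float = 0.2
    replacement_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.anatomy_depth < 1:
            raise ValueError("anatomy depth must be >= 1")
        if self.overlap_fraction > self.eq_coverage:
            raise ValueError("overlap fraction cannot exceed EQ coverage")
        for rate in (self.eq_coverage, self.overlap_fraction, self.synonym_fraction,
                     self.dropout_rate, self.replacement_rate, self.extra_part_of_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted truths of one generated study.

    ``alignment`` holds exactly the cross-species pairs built from
    identical (entity, quality) templates — what axiomatic reasoning
    can recover.  ``lexical_pairs`` are additional pairs marked only by
    a shared synonym.  ``translation`` maps species-A classes to their
    species-B counterparts over both kinds of pair.  ``associations``
    are the causal gene-disease pairs.
    """

    alignment: Alignment
    lexical_pairs: Set[Tuple[str, str]]
    translation: Dict[str, str]
    associations: Set[Tuple[str, str]]


def _anat(i: int) -> str:
    return f"{ANATOMY_PREFIX}:{i:07d}"


def _qual(i: int) -> str:
    return f"{QUALITY_PREFIX}:{i:07d}"


def generate_support(spec: FixtureSpec) -> OntologySnapshot:
    """Generate the anatomy + quality support ontology."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    snap = OntologySnapshot()
    cfg = fixture_rewrite_config()
    snap.add_role(cfg.part_of, transitive=True, reflexive=True)
    for role in (cfg.has_part, cfg.inheres_in, cfg.has_quality, cfg.has_modifier):
        snap.add_role(role)

    root = _anat(1)
    snap.add_class(root, "body")
    levels = [[root]]
    next_id = 2
    for depth in range(spec.anatomy_depth):
        level: list[str] = []
        for parent in levels[-1]:
            for _ in range(spec.anatomy_branching):
                c = _anat(next_id)
                next_id += 1
                snap.add_class(c, f"anatomical structure {next_id - 1}")
                snap.axioms.append(SubClassOf(Named(c), Named(parent)))
                snap.axioms.append(SubClassOf(Named(c), some(cfg.part_of, Named(parent))))
                level.append(c)
        levels.append(level)
    # extra cross part-of edges among non-root classes, acyclic by index order
    all_anat = [c for lvl in levels for c in lvl]
    for c in all_anat[1:]:
        if rng.random() < spec.extra_part_of_prob:
            target = all_anat[int(rng.integers(0, all_anat.index(c)))]
            snap.axioms.append(SubClassOf(Named(c), some(cfg.part_of, Named(target))))

    snap.add_class(QUALITY_ROOT, "quality")
    for i in range(1, spec.n_qualities + 1):
        q = _qual(i)
        snap.add_class(q, f"quality {i}")
        snap.axioms.append(SubClassOf(Named(q), Named(QUALITY_ROOT)))
    snap.add_class(ABNORMAL, "abnormal")
    snap.axioms.append(SubClassOf(Named(ABNORMAL), Named(QUALITY_ROOT)))
    return snap


def _eq_axiom(phenotype: str, entity: str, quality: str,
              cfg: RewriteConfig) -> EquivalentClasses:
    return EquivalentClasses([
        Named(phenotype),
        some(cfg.has_part, conj(Named(quality),
                                some(cfg.inheres_in, Named(entity)),
                                some(cfg.has_modifier, Named(ABNORMAL)))),
    ])


def generate_species_pair(spec: FixtureSpec,
                          support: OntologySnapshot
                          ) -> Tuple[OntologySnapshot, OntologySnapshot, GroundTruth]:
    """Generate the two species phenotype ontologies and their ground truth.

    Class ``i`` of species A corresponds to class ``i`` of species B
    for planted pairs; the first ``round(f * n)`` indices share an EQ
    template (the reasoned ground truth), the next ``round(synonym_
    fraction * n)`` share only a synonym string (the lexical ground
    truth).  EQ coverage is filled per species with species-unique
    templates, so no unplanned definition collisions occur.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    cfg = fixture_rewrite_config()
    n = spec.n_phenotypes_per_species
    n_eq = round(spec.eq_coverage * n)
    n_shared = round(spec.overlap_fraction * n)
    n_lex = round(spec.synonym_fraction * n)
    if n_shared + n_lex > n:
        raise ValueError("overlap + synonym fractions exceed 1")

    anatomy = sorted(c for c in support.classes if c.startswith(ANATOMY_PREFIX + ":"))
    qualities = sorted(c for c in support.classes
                       if c.startswith(QUALITY_PREFIX + ":")
                       and c not in (QUALITY_ROOT, ABNORMAL))
    grid = [(e, q) for e in anatomy for q in qualities]
    need = n_shared + 2 * (n_eq - n_shared)
    if need > len(grid):
        raise ValueError(f"template grid too small: need {need}, have {len(grid)}")
    chosen = rng.choice(len(grid), size=need, replace=False)
    templates = [grid[int(i)] for i in chosen]
    shared = templates[:n_shared]
    unique_a = templates[n_shared:n_shared + (n_eq - n_shared)]
    unique_b = templates[n_shared + (n_eq - n_shared):]

    # one is_a topology, mirrored in both species: sister phenotype
    # ontologies share their subclass backbone, and mirroring keeps the
    # entailed cross-species equivalences exactly at the planted pairs
    parent_idx = [None if (i == 0 or rng.random() < 0.5)
                  else int(rng.integers(0, i)) for i in range(n)]

    def build(prefix: str, unique: list) -> OntologySnapshot:
        snap = OntologySnapshot()
        for role in (cfg.has_part, cfg.inheres_in, cfg.has_modifier, cfg.has_quality):
            snap.add_role(role)
        root = f"{prefix}:0000000"
        snap.add_class(root, f"{prefix.lower()} phenotype")
        classes = []
        for i in range(1, n + 1):
            c = f"{prefix}:{i:07d}"
            snap.add_class(c, f"{prefix.lower()} phenotype {i}")
            classes.append(c)
        for i, c in enumerate(classes):
            parent = root if parent_idx[i] is None else classes[parent_idx[i]]
            snap.axioms.append(SubClassOf(Named(c), Named(parent)))
        for i, (e, q) in enumerate(shared):
            snap.axioms.append(_eq_axiom(classes[i], e, q, cfg))
        for i, (e, q) in enumerate(unique):
            snap.axioms.append(_eq_axiom(classes[n_shared + i], e, q, cfg))
        snap.classes |= snap.referenced_curies()
        return snap

    snap_a = build(SPECIES_A, unique_a)
    snap_b = build(SPECIES_B, unique_b)

    planted = set()
    translation: Dict[str, str] = {}
    for i in range(1, n_shared + 1):
        ca, cb = f"{SPECIES_A}:{i:07d}", f"{SPECIES_B}:{i:07d}"
        planted.add(Mapping(ca, cb, "equiv", None, "reasoned"))
        translation[ca] = cb
    lexical_pairs: Set[Tuple[str, str]] = set()
    for i in range(n_shared + 1, n_shared + n_lex + 1):
        ca, cb = f"{SPECIES_A}:{i:07d}", f"{SPECIES_B}:{i:07d}"
        syn = f"shared phenotype term {i}"
        snap_a.synonyms.setdefault(ca, set()).add(syn)
        snap_b.synonyms.setdefault(cb, set()).add(syn)
        lexical_pairs.add((ca, cb))
        translation[ca] = cb
    truth = GroundTruth(
        alignment=Alignment(SPECIES_A, SPECIES_B, planted),
        lexical_pairs=lexical_pairs,
        translation=translation,
        associations=set(),
    )
    return snap_a, snap_b, truth


def generate_corpora(spec: FixtureSpec, truth: GroundTruth
                     ) -> Tuple[AnnotationCorpus, AnnotationCorpus, GroundTruth]:
    """Generate gene/disease corpora with planted causal associations.

    Genes annotate species-A classes drawn from the translatable pool;
    each disease copies its causal gene's annotation set translated to
    species B, then drops each class with the dropout rate (always
    keeping at least one) and replaces each survivor with a random
    species-B class at the replacement rate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    pool = sorted(truth.translation)
    if not pool:
        raise ValueError("no translatable classes: overlap and synonym fractions are both 0")
    k = min(spec.annotations_per_entity, len(pool))
    all_b = [f"{SPECIES_B}:{i:07d}" for i in range(1, spec.n_phenotypes_per_species + 1)]

    genes: Dict[str, Set[str]] = {}
    for i in range(1, spec.n_genes + 1):
        gid = f"GENE:{i:04d}"
        picks = rng.choice(len(pool), size=k, replace=False)
        genes[gid] = {pool[int(j)] for j in picks}

    gene_ids = sorted(genes)
    diseases: Dict[str, Set[str]] = {}
    associations: Set[Tuple[str, str]] = set()
    for i in range(1, spec.n_diseases + 1):
        did = f"DIS:{i:04d}"
        causal = gene_ids[int(rng.integers(0, len(gene_ids)))]
        translated = sorted(truth.translation[c] for c in genes[causal])
        kept = [c for c in translated if rng.random() >= spec.dropout_rate]
        if not kept:
            kept = [translated[int(rng.integers(0, len(translated)))]]
        final = {c if rng.random() >= spec.replacement_rate
                 else all_b[int(rng.integers(0, len(all_b)))]
                 for c in kept}
        diseases[did] = final
        associations.add((causal, did))

    truth_out = GroundTruth(truth.alignment, truth.lexical_pairs,
                            truth.translation, associations)
    return (AnnotationCorpus(genes, "gene"),
            AnnotationCorpus(diseases, "disease"),
            truth_out)


def generate_all(spec: FixtureSpec):
    """Convenience: support, species pair, corpora and ground truth."""
    support = generate_support(spec)
    snap_a, snap_b, truth = generate_species_pair(spec, support)
    genes, diseases, truth = generate_corpora(spec, truth)
    return support, snap_a, snap_b, genes, diseases, truth
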