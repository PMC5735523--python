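# Methods

## Scope and representation

phenomatch works in a fixed OWL 2 EL fragment: named classes,
conjunction and existential restriction, plus role hierarchies,
transitive roles and reflexive roles. Nothing the pipeline generates
needs more — EQ definitions, their entity-first rewrites, grouping
classes and mapping axioms all live in this fragment — and restricting
to it keeps classification polynomial and the reasoner small enough to
verify against a brute-force oracle. Disjointness axioms are
representable but deliberately removed before classification:
independently developed anatomy and phenotype ontologies disagree on
disjointness often enough that keeping them manufactures unsatisfiable
classes; with them stripped the fragment has no bottom concept and the
reasoner needs no clash rule. Expressions are canonicalized on
construction (conjunctions flattened, deduplicated, sorted), so
structural equality is decidable by `==` and serialization is
deterministic.

Two concrete syntaxes are supported: OBO 1.4 flat files (stanza
parsing delegated to obonet; genus/differentia `intersection_of`
blocks become equivalence axioms) and a restricted Functional-Style
Syntax subset with a hand-written recursive-descent parser and a
sorted, byte-stable writer. Identifiers are normalized to upper-case
`PREFIX:LOCAL` CURIEs; OBO PURLs and underscore forms are accepted.
Obsolete OBO terms are dropped and `alt_id`s kept as cross-references,
so stale identifiers in mapping files still resolve without creating
phantom classes.

## EQ rewriting

Detection matches `EquivalentClasses(P, 'has part' some (Q and
('inheres in' some E) [and ('has modifier' some M)]))` up to conjunct
order, with Q a named class in the quality namespace and E any
expression (a named entity, or a conjunction for constrained entities
such as *'copper atom' and 'part of' some brain*). The rewrite emits
exactly two axioms per definition: the entity-first phenotype
equivalence (modifier dropped, kept only as metadata — phenotype
ontologies attach "abnormal" almost uniformly, so it carries no
discriminating signal in the rewritten classification) and a grouping
equivalence for the definition's primary entity. For conjunction
entities the primary entity is the first named conjunct in canonical
order — a declared tie-break; if the entity has no top-level named
conjunct, no grouping class is minted. Grouping CURIEs are a pure
function of the entity (`PHENO:G-<prefix>-<local>` by default), so
phenotypes sharing an entity share one grouping class, and the rewrite
is idempotent: the rewritten pattern uses has-quality rather than
inheres-in and is never re-detected. Original EQ axioms are replaced
rather than kept (a `keep_original` flag restores them), because
keeping both re-imports the quality-first classification the rewrite
exists to avoid. Grouping classes are minted for process (GO)
entities exactly as for anatomical ones, using the same part-of role.

The integrated build merges the rewritten phenotype ontologies with
disjointness-stripped support ontologies and any injected mapping
axioms, flags 'part of' transitive **and** reflexive (reflexivity is
what puts a tongue phenotype under the tongue grouping class itself,
not only under groupings of its containing structures), and fails on
conflicting class declarations across inputs.

## The reasoner

Classification is the standard two-phase EL procedure. Normalization
assigns one fresh atomic name per distinct complex subexpression —
keyed by structure, so two classes with the same definition share its
internal name and their equivalence falls out of told axioms — and
reduces everything to `A ⊑ B`, `A1 ⊓ … ⊓ An ⊑ B`, `A ⊑ ∃r.B` and
`∃r.A ⊑ B`. Saturation is a worklist fixpoint over completion rules:
told subsumption, conjunction firing, existential introduction and
elimination (role-exact, with edges closed under the role hierarchy at
insertion), transitivity composition, and the reflexivity rule
`X ⊑ ∃r.X` for every atom and reflexive role. The fixpoint is
set-based, hence independent of rule-application order. The derived
preorder on named classes is condensed into equivalence groups
(strongly connected components) and a transitively reduced DAG of
direct edges (networkx). Role chains beyond transitivity, nominals and
concrete domains are out of scope.

Correctness is checked two ways: hand-built worked examples with known
entailments, and exact agreement with an independent oracle — an
unindexed exhaustive fixpoint with its own normalization code that
rescans every rule until nothing changes — on hundreds of seeded
random EL ontologies (≤ 30 classes, ≤ 60 axioms, all features
exercised).

## Alignment

Mappings are typed (equiv / sub / super) with optional score and a
provenance tag. Equivalences are canonicalized to the
lexicographically smaller prefix; only `sub` is materialized, `super`
being its inverse view, which avoids double counting. Scored mappings
convert to axioms only when the score is **strictly greater** than the
threshold (default 0.7); scoreless curated mappings always pass.
Extraction mines a classified taxonomy for cross-prefix pairs sharing
an equivalence group (equiv) and strictly subsumed cross-prefix pairs
(sub), restricted to the two requested namespaces — minted grouping
classes and support-ontology classes never appear in an alignment.
The built-in lexical matcher is intentionally a floor: exact
case-folded, punctuation-normalized string equality over labels (1.0)
and synonyms (0.9). Production lexical mappings are expected to come
from a dedicated matching system via the TSV carrier.

## Semantic similarity and evaluation

Information content is `-ln` of annotation frequency under the
true-path rule, pooling gene and disease corpora by default (the
estimate is configurable to either side; natural log). Classes with no
annotation mass get the finite cap `ln(N) + 1` — one unit above the
most informative annotated class — so noise classes cannot generate
unbounded similarities. Resnik similarity is the maximum IC over
common ancestors (0 when none exists); BMA is the symmetric two-sided
average of row and column best matches. Ranking scores every
gene-disease pair; ties in per-disease rankings break by stable entity
id. AUROC uses the rank-sum formulation with midrank ties, reported
both pooled over all pairs and macro-averaged per disease (the two
orientations answer different questions; neither is privileged).

## The synthetic study

The generator is a pure function of a `FixtureSpec` (same spec,
byte-identical outputs). It emulates: an anatomy that is an is_a tree
whose children are also part-of their parents, with occasional extra
part-of edges; a flat quality tree plus an "abnormal" class; two
species ontologies (SPA/SPB) whose class *i* corresponds to class *i*
of the partner for planted pairs — the first `round(f·n)` indices
share an (entity, quality) EQ template verbatim (the reasoned ground
truth), the next `round(synonym_fraction·n)` share only a synonym
string (the lexical ground truth), and remaining EQ coverage is filled
with species-unique templates. The is_a backbone is drawn once and
mirrored in both species: sister phenotype ontologies genuinely share
structure, and mirroring ensures the entailed cross-species
equivalences are exactly the planted pairs (opposed is_a directions
would compose with planted equivalences into extra, unplanned
equivalence groups). Labels share no strings across species unless
synonyms are planted, keeping the reasoned and lexical recovery paths
separable.

Corpora: genes annotate species-A classes drawn from the translatable
pool; each disease copies its causal gene's annotations translated to
species B, then drops each class at the dropout rate (always keeping
one) and replaces survivors at the replacement rate with random
species-B classes — mirroring the model-organism-to-human-disease
comparison, where disease annotations are noisy, incomplete echoes of
a causal gene's phenotypes.

Defaults model a small study: 40-class anatomy (depth 3, branching 3),
8 qualities, 40 phenotypes per species with 50 % EQ coverage (roughly
the constrained fraction of real species phenotype ontologies), 30 %
template overlap, 50 genes and 30 diseases with 8 annotations each,
20 % dropout, 10 % replacement. What passing tests show is internal
consistency and recoverability under these controlled conditions; the
fixtures do not model real ontologies' uneven depth, synonym richness,
inter-annotator variation, or the heavily skewed annotation
frequencies of clinical corpora, so absolute AUROC values here do not
transfer to real data — only the orderings (mapped ≥ plain ≫ null) and
the exact-recovery property are the claims under test. The ranking
test that asserts the causal gene tops ≥ 90 % of disease rankings uses
a deliberately discriminative configuration (120 phenotypes per
species, 50 % overlap, dropout only) at a fixed seed, with the
threshold recorded from a pilot run at that seed.

## Problem sizes and numerics

Test and acceptance runs use desk-scale inputs — hundreds of classes,
dozens of entities — chosen so the whole suite and the acceptance
script each complete in about a minute on one CPU; the algorithms are
set-based and scale to real ontologies, but no claims at that scale
are made here. Floating-point comparisons in tests use relative
tolerances; similarity code has no iterative numerics. Degenerate
inputs (empty corpora, empty class sets, all-positive gold standards,
unknown classes) raise errors rather than returning defaults.
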