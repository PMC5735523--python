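"""Gene-disease prioritization on a synthetic two-species study.

Generates a seeded study (anatomy + qualities, two species phenotype
ontologies with planted cross-species pairs, gene/disease corpora with
planted causal associations), then compares three integrated
ontologies on recovering the causal genes by BMA-Resnik similarity:

* plain   — rewritten axioms only, no cross-species mappings;
* mapped  — plus lexical mappings found by the exact-string baseline;
* null    — mapped ontology but with gene labels shuffled.
"""

import numpy as np

from phenomatch import (
    AnnotationCorpus,
    build_integrated,
    compute_ic,
    exact_label_match,
    extract_mappings,
    generate_all,
    mappings_to_axioms,
    rank_associations,
    roc_auc,
    saturate,
)
from phenomatch.simulate import FixtureSpec, fixture_rewrite_config

spec = FixtureSpec(seed=11, synonym_fraction=0.2)
support, species_a, species_b, genes, diseases, truth = generate_all(spec)
print(f"study: {spec.n_genes} genes, {spec.n_diseases} diseases, "
      f"{len(truth.alignment.equiv)} reasoned + {len(truth.lexical_pairs)} "
      f"lexical planted pairs")

config = fixture_rewrite_config()


def evaluate(mapping_axioms, gene_corpus):
    merged = build_integrated([species_a, species_b], [support],
                              mapping_axioms, config)
    taxonomy = saturate(merged)
    g, d = gene_corpus.restrict(taxonomy), diseases.restrict(taxonomy)
    ic = compute_ic(g, d, taxonomy)
    result = rank_associations(g, d, ic, taxonomy)
    pooled, macro = roc_auc(result, truth.associations)
    return pooled, macro


lexical = exact_label_match(species_a, species_b)
axioms, _ = mappings_to_axioms(lexical)
print(f"lexical baseline found {len(lexical)} cross-species mappings")

plain = evaluate([], genes)
mapped = evaluate(axioms, genes)
rng = np.random.default_rng(2)
ids = genes.entities
perm = [ids[i] for i in rng.permutation(len(ids))]
null = evaluate(axioms, AnnotationCorpus(
    {new: genes.annotations[old] for new, old in zip(ids, perm)}, "gene"))

print(f"\nAUROC (pooled, per-disease macro):")
print(f"  plain  (no mappings):    {plain[0]:.3f}  {plain[1]:.3f}")
print(f"  mapped (+lexical):       {mapped[0]:.3f}  {mapped[1]:.3f}")
print(f"  null   (shuffled genes): {null[0]:.3f}  {null[1]:.3f}")
print("\nAUROC is the probability that a true causal gene-disease pair")
print("outranks a random non-causal one; 0.5 is chance.  Mappings add the")
print("cross-species links reasoning alone cannot see, raising the AUROC.")
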