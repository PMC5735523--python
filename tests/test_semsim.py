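"""Information content, Resnik, BMA and ROC evaluation."""

import math

import numpy as np
import pytest

from phenomatch.model import Named, OntologySnapshot, SubClassOf
from phenomatch.reasoner import saturate
from phenomatch.semsim import (
    AnnotationCorpus,
    ICTable,
    bma,
    compute_ic,
    rank_associations,
    resnik,
    roc_auc,
)


def _tree(edges):
    snap = OntologySnapshot()
    for a, b in edges:
        snap.add_class(a)
        snap.add_class(b)
        snap.axioms.append(SubClassOf(Named(a), Named(b)))
    return saturate(snap)


@pytest.fixture
def small_tree():
    #        root
    #       /    \
    #      L       R
    #    /  \       \
    #   L1   L2      R1
    return _tree([("T:L", "T:root"), ("T:R", "T:root"),
                  ("T:L1", "T:L"), ("T:L2", "T:L"), ("T:R1", "T:R")])


def _corpus(side, **annotations):
    return AnnotationCorpus({k: set(v) for k, v in annotations.items()}, side)


def test_ic_root_is_zero(small_tree):
    genes = _corpus("gene", g1=["T:root"])
    diseases = _corpus("disease", d1=["T:root"])
    ic = compute_ic(genes, diseases, small_tree)
    assert ic["T:root"] == 0.0


def test_ic_closed_form_half(small_tree):
    """One of two entities on leaf L1, the other on a disjoint branch."""
    genes = _corpus("gene", g1=["T:L1"], g2=["T:R1"])
    diseases = _corpus("disease")
    ic = compute_ic(genes, diseases, small_tree)
    assert ic["T:L1"] == pytest.approx(-math.log(0.5))
    assert ic["T:root"] == 0.0


def test_ic_cap_for_unannotated(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:L2"])
    diseases = _corpus("disease")
    ic = compute_ic(genes, diseases, small_tree)
    assert ic["T:R1"] == ic.cap == math.log(2) + 1.0


def test_ic_empty_corpus_errors(small_tree):
    with pytest.raises(ValueError):
        compute_ic(_corpus("gene"), _corpus("disease"), small_tree)


def test_ic_monotone_along_subsumption(small_tree):
    rng = np.random.default_rng(4)
    classes = sorted(small_tree.classes)
    genes = _corpus("gene", **{f"g{i}": [classes[rng.integers(len(classes))]]
                               for i in range(20)})
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    for c in classes:
        for a in small_tree.ancestors(c):
            assert ic[a] <= ic[c] + 1e-12


def test_ic_matches_descendant_enumeration_oracle(small_tree):
    """Frequency counting equals the brute-force descendant-set scan."""
    rng = np.random.default_rng(8)
    classes = sorted(small_tree.classes)
    ann = {f"e{i}": {classes[rng.integers(len(classes))],
                     classes[rng.integers(len(classes))]} for i in range(50)}
    genes = AnnotationCorpus(ann, "gene")
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    for c in classes:
        desc = small_tree.descendants(c)
        n = sum(1 for e, s in ann.items() if s & desc)
        expected = ic.cap if n == 0 else -math.log(n / 50)
        assert ic[c] == pytest.approx(expected)


def test_resnik_self_similarity(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:L2"])
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    assert resnik("T:L1", "T:L1", ic, small_tree) == pytest.approx(ic["T:L1"])


def test_resnik_disjoint_branches_zero(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:R1"])
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    # only shared ancestor is the root, annotated by everything
    assert resnik("T:L1", "T:R1", ic, small_tree) == 0.0


def test_resnik_bounded_by_min_ic_and_symmetric(small_tree):
    rng = np.random.default_rng(6)
    classes = sorted(small_tree.classes)
    genes = _corpus("gene", **{f"g{i}": [classes[rng.integers(len(classes))]]
                               for i in range(12)})
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    for c1 in classes:
        for c2 in classes:
            r = resnik(c1, c2, ic, small_tree)
            assert r == pytest.approx(resnik(c2, c1, ic, small_tree))
            assert r <= min(ic[c1], ic[c2]) + 1e-12


def test_resnik_matches_exhaustive_scan(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:L2"], g3=["T:R1"])
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    for c1 in small_tree.classes:
        for c2 in small_tree.classes:
            common = small_tree.ancestors(c1) & small_tree.ancestors(c2)
            expected = max((ic[c] for c in common), default=0.0)
            assert resnik(c1, c2, ic, small_tree) == pytest.approx(expected)


def test_bma_identity_sets(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:L2"], g3=["T:R1"])
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    s = {"T:L1", "T:R1"}
    assert bma(s, s, ic, small_tree) == pytest.approx(
        np.mean([ic["T:L1"], ic["T:R1"]]))


def test_bma_singletons_reduce_to_resnik(small_tree):
    genes = _corpus("gene", g1=["T:L1"], g2=["T:L2"])
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    assert bma({"T:L1"}, {"T:L2"}, ic, small_tree) == pytest.approx(
        resnik("T:L1", "T:L2", ic, small_tree))


def test_bma_symmetric_and_matches_double_loop(small_tree):
    rng = np.random.default_rng(9)
    classes = sorted(small_tree.classes)
    genes = _corpus("gene", **{f"g{i}": [classes[rng.integers(len(classes))]]
                               for i in range(10)})
    ic = compute_ic(genes, _corpus("disease"), small_tree)
    A = {classes[i] for i in rng.choice(len(classes), 5)}
    B = {classes[i] for i in rng.choice(len(classes), 4)}
    got = bma(A, B, ic, small_tree)
    assert got == pytest.approx(bma(B, A, ic, small_tree))
    row = np.mean([max(resnik(a, b, ic, small_tree) for b in B) for a in A])
    col = np.mean([max(resnik(a, b, ic, small_tree) for a in A) for b in B])
    assert got == pytest.approx(0.5 * (row + col))


def test_bma_empty_set_errors(small_tree):
    ic = ICTable({}, 1)
    with pytest.raises(ValueError):
        bma(set(), {"T:L1"}, ic, small_tree)


def test_rank_associations_identical_sets_top(small_tree):
    genes = _corpus("gene", g1=["T:L1", "T:L2"], g2=["T:R1"])
    diseases = _corpus("disease", d1=["T:L1", "T:L2"])
    ic = compute_ic(genes, diseases, small_tree)
    result = rank_associations(genes, diseases, ic, small_tree)
    assert result.ranking_for("d1")[0] == "g1"
    assert result.rank_of("g1", "d1") == 1


def test_rank_matrix_matches_bma(small_tree):
    """The vectorized matrix equals per-pair BMA calls."""
    rng = np.random.default_rng(10)
    classes = sorted(small_tree.classes)
    genes = _corpus("gene", **{f"g{i}": set(classes[j] for j in
                                            rng.choice(len(classes), 3, replace=False))
                               for i in range(4)})
    diseases = _corpus("disease", **{f"d{i}": set(classes[j] for j in
                                                  rng.choice(len(classes), 2, replace=False))
                                     for i in range(3)})
    ic = compute_ic(genes, diseases, small_tree)
    result = rank_associations(genes, diseases, ic, small_tree)
    for g in genes.entities:
        for d in diseases.entities:
            expected = bma(genes.annotations[g], diseases.annotations[d],
                           ic, small_tree)
            assert result.scores.loc[g, d] == pytest.approx(expected)


def test_roc_perfect_separation(small_tree):
    import pandas as pd

    from phenomatch.semsim import RankingResult
    scores = pd.DataFrame([[1.0, 0.1], [0.2, 0.9]],
                          index=["g1", "g2"], columns=["d1", "d2"])
    pooled, macro = roc_auc(RankingResult(scores), {("g1", "d1"), ("g2", "d2")})
    assert pooled == 1.0 and macro == 1.0


def test_roc_random_scores_near_half():
    import pandas as pd

    from phenomatch.semsim import RankingResult
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(40)]
    diseases = [f"d{i}" for i in range(40)]
    scores = pd.DataFrame(rng.random((40, 40)), index=genes, columns=diseases)
    gold = {(genes[int(rng.integers(40))], d) for d in diseases}
    pooled, macro = roc_auc(RankingResult(scores), gold)
    assert abs(pooled - 0.5) < 0.07


def test_roc_matches_pair_counting_oracle():
    import pandas as pd

    from phenomatch.semsim import RankingResult
    rng = np.random.default_rng(13)
    scores = pd.DataFrame(rng.integers(0, 5, size=(10, 10)).astype(float),
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"d{i}" for i in range(10)])
    gold = {(f"g{i}", f"d{j}") for i, j in rng.integers(0, 10, size=(15, 2))}
    pooled, _ = roc_auc(RankingResult(scores), gold)
    flat = scores.to_numpy().ravel()
    labels = np.zeros_like(flat, dtype=bool)
    gidx = {g: i for i, g in enumerate(scores.index)}
    didx = {d: j for j, d in enumerate(scores.columns)}
    for g, d in gold:
        labels[gidx[g] * 10 + didx[d]] = True
    pos, neg = flat[labels], flat[~labels]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert pooled == pytest.approx(conc / (len(pos) * len(neg)))


def test_roc_degenerate_gold_errors(small_tree):
    import pandas as pd

    from phenomatch.semsim import RankingResult
    scores = pd.DataFrame([[1.0]], index=["g1"], columns=["d1"])
    with pytest.raises(ValueError):
        roc_auc(RankingResult(scores), set())
    with pytest.raises(ValueError):
        roc_auc(RankingResult(scores), {("g1", "d1")})  # all pairs positive


def test_corpus_restrict_drops_unknown(small_tree):
    corpus = _corpus("gene", g1=["T:L1", "XX:404"], g2=["YY:404"])
    restricted = corpus.restrict(small_tree)
    assert restricted.annotations == {"g1": {"T:L1"}}
    assert restricted.n_dropped == 2
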