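"""Information content, Resnik/BMA similarity and ranking evaluation.

Gene-disease prioritization over an integrated phenotype taxonomy:
annotation corpora (gene -> phenotype classes, disease -> phenotype
classes) define per-class information content; Resnik similarity
scores class pairs by the information content of their most
informative common ancestor; the Best Matching Average combines the
pairwise scores into a set-level similarity; ranking quality against a
gold-standard association list is summarized as AUROC.

Information content uses the standard true-path rule: an entity
annotated to a class counts toward every ancestor of that class.  The
default corpus pools genes and diseases; natural log throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .reasoner import Taxonomy


@dataclass
class AnnotationCorpus:
    """Entity -> phenotype-class-set associations for one side."""

    annotations: Dict[str, Set[str]]
    side: str = "gene"
    n_dropped: int = 0

    @property
    def entities(self) -> list:
        return sorted(self.annotations)

    def restrict(self, taxonomy: Taxonomy) -> "AnnotationCorpus":
        """Drop annotation classes not present in the taxonomy (counted)."""
        known = taxonomy.classes
        dropped = 0
        kept: Dict[str, Set[str]] = {}
        for ent, classes in self.annotations.items():
            resolved = {c for c in classes if c in known}
            dropped += len(classes) - len(resolved)
            if resolved:
                kept[ent] = resolved
        return AnnotationCorpus(kept, self.side, n_dropped=dropped)


def load_annotations_tsv(path: str, side: str = "gene",
                         entity_col: int = 0, class_col: int = 1) -> AnnotationCorpus:
    """Read an annotation TSV (one entity/class pair per line).

    ``entity_col``/``class_col`` adapt the reader to multi-column
    layouts such as the HPO phenotype-annotation format.  Lines
    starting with ``#`` are ignored.
    """
    from .model import normalize_id
    ann: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            ann.setdefault(parts[entity_col], set()).add(normalize_id(parts[class_col]))
    return AnnotationCorpus(ann, side)


def write_annotations_tsv(corpus: AnnotationCorpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ent in sorted(corpus.annotations):
            for c in sorted(corpus.annotations[ent]):
                fh.write(f"{ent}\t{c}\n")


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Per-class information content, -ln of annotation frequency.

    Classes carrying no annotation mass get a finite cap,
    ``ln(corpus_size) + 1``, one unit above the most informative
    annotated class, so noise classes cannot produce unbounded scores.
    """

    ic: Dict[str, float]
    corpus_size: int

    @property
    def cap(self) -> float:
        return math.log(self.corpus_size) + 1.0

    def __getitem__(self, c: str) -> float:
        return self.ic.get(c, self.cap)


def compute_ic(genes: AnnotationCorpus, diseases: AnnotationCorpus,
               taxonomy: Taxonomy, corpus: str = "pooled",
               log_base: Optional[float] = None) -> ICTable:
    """Information content from annotation frequency under true-path propagation.

    ``corpus`` selects which side(s) define the frequency estimate:
    ``pooled`` (default), ``genes`` or ``diseases``.
    """
    sides = {"pooled": (genes, diseases), "genes": (genes,),
             "diseases": (diseases,)}.get(corpus)
    if sides is None:
        raise ValueError(f"unknown corpus selector {corpus!r}")
    counts: Dict[str, int] = {}
    total = 0
    for side in sides:
        for ent, classes in side.annotations.items():
            total += 1
            covered: Set[str] = set()
            for c in classes:
                covered |= taxonomy.ancestors(c)
            for c in covered:
                counts[c] = counts.get(c, 0) + 1
    if total == 0:
        raise ValueError("empty joint annotation corpus")
    scale = math.log(log_base) if log_base else 1.0
    ic = {c: -math.log(n / total) / scale for c, n in counts.items()}
    return ICTable(ic, total)


def resnik(c1: str, c2: str, ic: ICTable, taxonomy: Taxonomy) -> float:
    """IC of the most informative common ancestor; 0 without one."""
    common = taxonomy.ancestors(c1) & taxonomy.ancestors(c2)
    if not common:
        return 0.0
    return max(ic[c] for c in common)


def bma(set_a: Iterable[str], set_b: Iterable[str],
        ic: ICTable, taxonomy: Taxonomy) -> float:
    """Best Matching Average: symmetric two-sided average of best matches."""
    a, b = sorted(set(set_a)), sorted(set(set_b))
    if not a or not b:
        raise ValueError("BMA requires two non-empty class sets")
    sim = [[resnik(x, y, ic, taxonomy) for y in b] for x in a]
    row = sum(max(r) for r in sim) / len(a)
    col = sum(max(sim[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
    return 0.5 * (row + col)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    """Full gene x disease similarity matrix plus per-disease rankings."""

    scores: pd.DataFrame  # index: gene ids, columns: disease ids
    tie_break: str = "entity id (stable ascending)"

    def ranking_for(self, disease: str) -> list:
        col = self.scores[disease]
        return list(col.sort_values(ascending=False, kind="stable").index)

    def rank_of(self, gene: str, disease: str) -> int:
        """1-based rank of *gene* for *disease* (competition ranking on ties)."""
        col = self.scores[disease]
        return int((col > col[gene]).sum()) + 1


def _pairwise_resnik(classes_a: Sequence[str], classes_b: Sequence[str],
                     ic: ICTable, taxonomy: Taxonomy) -> np.ndarray:
    """Dense Resnik matrix between two class lists (shared-ancestor max)."""
    all_anc = sorted({a for c in list(classes_a) + list(classes_b)
                      for a in taxonomy.ancestors(c)})
    idx = {c: i for i, c in enumerate(all_anc)}
    ic_vec = np.array([ic[c] for c in all_anc])

    def incidence(classes: Sequence[str]) -> np.ndarray:
        m = np.zeros((len(classes), len(all_anc)), dtype=bool)
        for i, c in enumerate(classes):
            for a in taxonomy.ancestors(c):
                m[i, idx[a]] = True
        return m

    A, B = incidence(classes_a), incidence(classes_b)
    out = np.zeros((len(classes_a), len(classes_b)))
    neg = np.full(len(all_anc), -np.inf)
    for i in range(len(classes_a)):
        masked = np.where(A[i], ic_vec, neg)          # ic over ancestors of a_i
        vals = np.where(B, masked, -np.inf).max(axis=1)
        out[i] = np.where(np.isneginf(vals), 0.0, vals)
    return out


def rank_associations(genes: AnnotationCorpus, diseases: AnnotationCorpus,
                      ic: ICTable, taxonomy: Taxonomy) -> RankingResult:
    """Score every gene-disease pair with BMA-Resnik similarity."""
    genes = genes.restrict(taxonomy)
    diseases = diseases.restrict(taxonomy)
    gene_ids, disease_ids = genes.entities, diseases.entities
    classes_g = sorted({c for s in genes.annotations.values() for c in s})
    classes_d = sorted({c for s in diseases.annotations.values() for c in s})
    gi = {c: i for i, c in enumerate(classes_g)}
    di = {c: i for i, c in enumerate(classes_d)}
    R = _pairwise_resnik(classes_g, classes_d, ic, taxonomy)

    scores = np.zeros((len(gene_ids), len(disease_ids)))
    gene_rows = {g: np.array([gi[c] for c in sorted(genes.annotations[g])])
                 for g in gene_ids}
    disease_cols = {d: np.array([di[c] for c in sorted(diseases.annotations[d])])
                    for d in disease_ids}
    for i, g in enumerate(gene_ids):
        sub_rows = R[gene_rows[g], :]
        for j, d in enumerate(disease_ids):
            sub = sub_rows[:, disease_cols[d]]
            scores[i, j] = 0.5 * (sub.max(axis=1).mean() + sub.max(axis=0).mean())
    return RankingResult(pd.DataFrame(scores, index=gene_ids, columns=disease_ids))


# ---------------------------------------------------------------------------
# ROC evaluation
# ---------------------------------------------------------------------------

def _auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank-sum formulation with midrank tie handling."""
    from scipy.stats import rankdata
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both positive and negative pairs")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(result: RankingResult,
            gold: Set[Tuple[str, str]]) -> Tuple[float, float]:
    """Pooled and per-disease macro-averaged AUROC against gold pairs.

    The pooled AUROC treats every (gene, disease) cell as one
    observation; the macro average computes one AUROC per disease that
    has both positives and negatives, then averages.
    """
    if not gold:
        raise ValueError("empty gold standard")
    genes = list(result.scores.index)
    diseases = list(result.scores.columns)
    gold = {(g, d) for g, d in gold if g in set(genes) and d in set(diseases)}
    if not gold:
        raise ValueError("gold standard references no scored entities")
    label_mat = np.zeros(result.scores.shape, dtype=bool)
    gidx = {g: i for i, g in enumerate(genes)}
    didx = {d: j for j, d in enumerate(diseases)}
    for g, d in gold:
        label_mat[gidx[g], didx[d]] = True
    score_mat = result.scores.to_numpy()
    pooled = _auc_from_scores(score_mat.ravel(), label_mat.ravel())
    per_disease = []
    for j in range(len(diseases)):
        labels = label_mat[:, j]
        if 0 < labels.sum() < len(labels):
            per_disease.append(_auc_from_scores(score_mat[:, j], labels))
    macro = float(np.mean(per_disease)) if per_disease else float("nan")
    return float(pooled), macro


def load_gold_tsv(path: str) -> Set[Tuple[str, str]]:
    gold: Set[Tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            g, d = line.split("\t")[:2]
            gold.add((g, d))
    return gold


def write_gold_tsv(gold: Set[Tuple[str, str]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g, d in sorted(gold):
            fh.write(f"{g}\t{d}\n")
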