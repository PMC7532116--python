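"""Building a model-ready input from a raw association p-value matrix.

Mirrors the matrix-construction pipeline of GO-guided literature mining
front-ends: given a full gene x GO-term p-value matrix and two disjoint
input gene lists, (1) pick, per list, the GO terms with the smallest
average p-value over that list; (2) pick candidate genes by the largest
average cosine similarity to the list's genes, computed over *all* GO
columns on a transformed p-value scale; (3) binarize the selected
sub-matrix at a p-value cutoff. The input genes become hard constraints
(list 1 -> cluster 1, list 2 -> cluster 2) and the candidates are the free
rows the model may assign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import (
    AssociationPValueMatrix,
    BinaryAssociationMatrix,
    ConstraintSet,
)

logger = logging.getLogger(__name__)

_TRANSFORMS = ("neg_log10", "one_minus_p", "raw")


@dataclass
class PreprocessConfig:
    """Tuning knobs of the matrix construction.

    ``go_ratio`` / ``candidate_ratio`` are counts per input gene (a list of
    m genes selects ceil(ratio * m) GO terms / candidates).
    ``similarity_transform`` sets the scale cosine similarity is computed
    on; the default -log10(p) makes strong associations large, so genes
    sharing strong GO associations score as similar.
    """

    cutoff: float = 0.1
    go_ratio: float = 1.0
    candidate_ratio: float = 2.0
    similarity_transform: str = "neg_log10"
    closed_cutoff: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        if self.go_ratio <= 0 or self.candidate_ratio <= 0:
            raise ValueError("ratios must be > 0")
        if self.similarity_transform not in _TRANSFORMS:
            raise ValueError(f"similarity_transform must be one of {_TRANSFORMS}")


def binarize_pvalues(
    P: AssociationPValueMatrix, cutoff: float, closed: bool = False
) -> BinaryAssociationMatrix:
    """x_ij = 1 iff p_ij < cutoff (strict by default; ``closed`` uses <=)."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    mask = P.values <= cutoff if closed else P.values < cutoff
    return BinaryAssociationMatrix(
        values=mask.astype(np.int8), gene_ids=list(P.gene_ids), go_ids=list(P.go_ids)
    )


def _gene_rows(P: AssociationPValueMatrix, gene_ids: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(P.gene_ids)}
    missing = [g for g in gene_ids if g not in index]
    if missing:
        raise ValueError(f"gene id(s) not in matrix: {missing}")
    return np.array([index[g] for g in gene_ids])


def rank_go_terms(
    P: AssociationPValueMatrix, input_gene_ids: list[str], n_select: int
) -> list[str]:
    """GO terms with the smallest average p over the input genes, ascending.

    Ties keep the original column order (stable sort).
    """
    if n_select > len(P.go_ids):
        raise ValueError("n_select exceeds the number of GO terms")
    rows = _gene_rows(P, input_gene_ids)
    avg = P.values[rows].mean(axis=0)
    order = np.argsort(avg, kind="stable")
    return [P.go_ids[j] for j in order[:n_select]]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos of the angle between two vectors: dot(a,b) / (|a| |b|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == "neg_log10":
        return -np.log10(np.clip(values, 1e-300, 1.0))
    if how == "one_minus_p":
        return 1.0 - values
    return values.copy()


def rank_candidate_genes(
    P_full: AssociationPValueMatrix,
    input_gene_ids: list[str],
    n_select: int,
    transform: str = "neg_log10",
) -> list[str]:
    """Non-input genes ranked by average cosine similarity to the input genes.

    Similarity is computed over *all* GO columns of ``P_full`` on the
    transformed p-value scale. Genes whose transformed row is constant
    carry no directional information and are excluded with a warning.
    """
    rows = _gene_rows(P_full, input_gene_ids)
    others = [g for g in P_full.gene_ids if g not in set(input_gene_ids)]
    if n_select > len(others):
        raise ValueError("n_select exceeds the number of non-input genes")
    V = _transform(P_full.values, transform)
    scores: list[tuple[float, int, str]] = []
    input_vecs = V[rows]
    for g in others:
        i = P_full.gene_ids.index(g)
        v = V[i]
        if np.ptp(v) == 0:
            logger.warning("excluding zero-information gene %r from candidate ranking", g)
            continue
        sims = [cosine_similarity(v, w) for w in input_vecs]
        scores.append((-float(np.mean(sims)), i, g))
    scores.sort()
    return [g for _, _, g in scores[:n_select]]


def build_palmer_input(
    P_full: AssociationPValueMatrix,
    gene_list_1: list[str],
    gene_list_2: list[str],
    config: PreprocessConfig | None = None,
) -> tuple[BinaryAssociationMatrix, ConstraintSet]:
    """Assemble the binary matrix and constraints from two input gene lists.

    Per list: ceil(go_ratio * |list|) GO terms by smallest average p and
    ceil(candidate_ratio * |list|) candidate genes by cosine similarity.
    GO-term and candidate selections are unioned (duplicates emitted once);
    rows are the input genes of both lists plus the candidate union, with
    list-1 genes constrained to cluster 1 and list-2 genes to cluster 2.
    """
    config = config or PreprocessConfig()
    overlap = sorted(set(gene_list_1) & set(gene_list_2))
    if overlap:
        raise ValueError(f"input gene lists overlap: {overlap}")

    go_sel: list[str] = []
    cand_sel: list[str] = []
    for genes in (gene_list_1, gene_list_2):
        n_go = math.ceil(config.go_ratio * len(genes))
        n_cand = math.ceil(config.candidate_ratio * len(genes))
        for t in rank_go_terms(P_full, genes, n_go):
            if t not in go_sel:
                go_sel.append(t)
        for g in rank_candidate_genes(
            P_full, genes, n_cand, config.similarity_transform
        ):
            if g not in cand_sel:
                cand_sel.append(g)
    cand_sel = [g for g in cand_sel if g not in set(gene_list_1) | set(gene_list_2)]

    row_ids = list(gene_list_1) + list(gene_list_2) + cand_sel
    rows = _gene_rows(P_full, row_ids)
    cols = np.array([P_full.go_ids.index(t) for t in go_sel])
    sub = AssociationPValueMatrix(
        values=P_full.values[np.ix_(rows, cols)], gene_ids=row_ids, go_ids=go_sel
    )
    X = binarize_pvalues(sub, config.cutoff, closed=config.closed_cutoff)
    assignments = {g: 1 for g in gene_list_1}
    assignments.update({g: 2 for g in gene_list_2})
    return X, ConstraintSet(assignments=assignments, n_clusters=2)
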