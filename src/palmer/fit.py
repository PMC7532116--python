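"""Initialization and the outer alternation of the two conditional EMs.

One outer iteration runs the constrained gene-side EM against the current
hard GO-term labels, takes the hard gene labels, then runs the GO-side EM
seeded with the gene EM's final block rates ``theta`` (the shared-parameter
handoff that couples the two sides). The alternation stops when neither
label vector changes, or after ``max_outer`` iterations.

GO-term clusters are initialized by Ward-linkage agglomerative clustering of
the columns under Euclidean distance; on binary vectors squared Euclidean
distance is the number of mismatching positions, so this is a natural first
grouping of GO terms. In unconstrained mode the gene clusters are seeded the
same way from the rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .conditional_em import (
    compute_gene_counts,
    run_gene_em,
    run_go_em,
)
from .types import (
    EPS,
    BinaryAssociationMatrix,
    CoClusterModel,
    ConstraintSet,
    FitResult,
    HardAssignment,
)

logger = logging.getLogger(__name__)


@dataclass
class FitOptions:
    """Knobs of the alternating fit."""

    K: int
    L: int
    tol: float = 1e-6
    max_inner: int = 200
    max_outer: int = 50
    constrained: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_inner < 1 or self.max_outer < 1:
            raise ValueError("max_inner and max_outer must be >= 1")


def _ward_labels(rows: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering, labels 1..n_clusters in order
    of first appearance."""
    if n_clusters > rows.shape[0]:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {rows.shape[0]} items"
        )
    if n_clusters == rows.shape[0]:
        return np.arange(1, n_clusters + 1)
    Z = linkage(rows.astype(float), method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel in order of first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return out.astype(np.int64)


def init_go_labels(X: BinaryAssociationMatrix | np.ndarray, L: int) -> np.ndarray:
    """Initial GO-term labels: Ward clustering of the p columns into L groups."""
    Xv = X.values if isinstance(X, BinaryAssociationMatrix) else np.asarray(X)
    return _ward_labels(Xv.T, L)


def init_gene_model(
    X: BinaryAssociationMatrix,
    go_labels: np.ndarray,
    constraints: ConstraintSet | None,
    K: int,
) -> CoClusterModel:
    """First block-rate estimate for the gene EM.

    Constrained mode: ``theta[k, l]`` is the mean of the constrained genes of
    cluster k over the columns of GO cluster l (every anchored cluster must
    have at least one constrained gene). Unconstrained mode: gene clusters
    are seeded by Ward clustering of the rows into K and theta comes from
    those blocks. alpha and beta start uniform.
    """
    L = int(np.max(go_labels))
    if constraints is not None:
        cvec = constraints.label_vector(X.gene_ids)
        missing = [k for k in range(1, K + 1) if not (cvec == k).any()]
        if missing:
            raise ValueError(f"no constrained gene for cluster(s) {missing}")
        gene_labels, mask = cvec, cvec > 0
    else:
        gene_labels = _ward_labels(X.values.astype(float), K)
        mask = np.ones(X.n_genes, dtype=bool)
    theta = _block_means(X.values[mask], gene_labels[mask], go_labels, K, L)
    return CoClusterModel(
        theta=theta, alpha=np.full(K, 1.0 / K), beta=np.full(L, 1.0 / L)
    )


def _block_means(
    X: np.ndarray, gene_labels: np.ndarray, go_labels: np.ndarray, K: int, L: int
) -> np.ndarray:
    counts = compute_gene_counts(X, go_labels, L)
    theta = np.empty((K, L))
    for k in range(1, K + 1):
        rows = gene_labels == k
        nk = rows.sum()
        denom = np.maximum(counts.n_l * nk, 1)
        theta[k - 1] = counts.y[rows].sum(axis=0) / denom
    return np.clip(theta, EPS, 1 - EPS)


def fit_palmer(
    X: BinaryAssociationMatrix,
    constraints: ConstraintSet | None,
    opts: FitOptions,
) -> FitResult:
    """Fit the constrained latent block model by alternating conditional EMs."""
    cons = constraints if opts.constrained else None
    if opts.constrained and constraints is None:
        raise ValueError("constrained fit requires a ConstraintSet")

    go_labels = init_go_labels(X, opts.L)
    model = init_gene_model(X, go_labels, cons, opts.K)

    trace: list[float] = []
    prev_gene: np.ndarray | None = None
    prev_go: np.ndarray | None = None
    converged = False
    n_outer = 0
    for t in range(opts.max_outer):
        n_outer = t + 1
        model, gene_resp, gene_labels, tr_g = run_gene_em(
            X, go_labels, model, cons, tol=opts.tol, max_inner=opts.max_inner
        )
        # theta handoff: the GO EM starts from the gene EM's final estimates
        model, go_resp, go_labels, tr_l = run_go_em(
            X, gene_labels, model, tol=opts.tol, max_inner=opts.max_inner
        )
        trace.extend(tr_g)
        trace.extend(tr_l)
        if (
            prev_gene is not None
            and np.array_equal(gene_labels, prev_gene)
            and np.array_equal(go_labels, prev_go)
        ):
            converged = True
            break
        prev_gene, prev_go = gene_labels, go_labels
    logger.info(
        "fit finished after %d outer iteration(s), converged=%s", n_outer, converged
    )
    return FitResult(
        model=model,
        assignment=HardAssignment(gene_labels=gene_labels, go_labels=go_labels),
        gene_responsibilities=gene_resp,
        go_responsibilities=go_resp,
        n_outer_iterations=n_outer,
        converged=converged,
        loglik_trace=trace,
    )
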