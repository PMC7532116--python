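"""Synthetic gene x GO-term datasets with a planted block structure.

The generator emulates GO-guided literature-mining data: genes fall into K
pathway clusters and GO terms into L clusters, where each gene cluster owns
one GO-term cluster and one (or more) GO-term clusters are shared across
gene clusters. Association p-values are Beta(alpha_i, 1) inside signal
blocks — the per-gene shape alpha_i is drawn uniformly from an
SNR-dependent range, so P(p < c) = c^alpha_i — and Uniform(0, 1) in the
background, then thresholded at a binarization cutoff. A random fraction of
genes per cluster is emitted as hard constraints, mimicking partially known
pathway membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import (
    AssociationPValueMatrix,
    BinaryAssociationMatrix,
    ConstraintSet,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Full description of one simulated study condition.

    Each non-shared GO cluster is owned by exactly one gene cluster: by
    default the first K non-shared GO clusters (in label order) map to gene
    clusters 1..K; ``go_owner`` overrides this.
    """

    n_genes: int
    n_go: int
    K: int
    L: int
    gene_cluster_probs: tuple[float, ...]
    go_cluster_probs: tuple[float, ...]
    signal_alpha_range: tuple[float, float]
    shared_alpha_range: tuple[float, float] = (0.0, 1.0)
    shared_go_clusters: frozenset[int] = frozenset()
    cutoff: float = 0.1
    constraint_fraction: float = 0.5
    seed: int | None = None
    go_owner: dict[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.gene_cluster_probs) != self.K or len(self.go_cluster_probs) != self.L:
            raise ValueError("cluster probability vectors inconsistent with K/L")
        for probs in (self.gene_cluster_probs, self.go_cluster_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p <= 0 for p in probs):
                raise ValueError("cluster probabilities must be a positive simplex")
        lo, hi = self.signal_alpha_range
        if not (0 < lo < hi < 1):
            raise ValueError("signal_alpha_range must satisfy 0 < lo < hi < 1")
        lo, hi = self.shared_alpha_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("shared_alpha_range must satisfy 0 <= lo < hi <= 1")
        self.shared_go_clusters = frozenset(int(l) for l in self.shared_go_clusters)
        if any(l < 1 or l > self.L for l in self.shared_go_clusters):
            raise ValueError("shared GO clusters must lie in 1..L")
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        if not (0 <= self.constraint_fraction <= 1):
            raise ValueError("constraint_fraction must lie in [0, 1]")
        if self.go_owner is None:
            own = [l for l in range(1, self.L + 1) if l not in self.shared_go_clusters]
            if len(own) < self.K:
                raise ValueError("not enough non-shared GO clusters to own")
            self.go_owner = {l: k + 1 for k, l in enumerate(own[: self.K])}
        bad = set(self.go_owner) & self.shared_go_clusters
        if bad:
            raise ValueError(f"GO cluster(s) {sorted(bad)} are both shared and owned")


@dataclass
class SimulatedDataset:
    """One simulated matrix with its generating truth."""

    X: BinaryAssociationMatrix
    P: AssociationPValueMatrix
    true_gene_labels: np.ndarray
    true_go_labels: np.ndarray
    constraints: ConstraintSet
    per_gene_alpha: np.ndarray


def _cluster_sizes(
    rng: np.random.Generator, n: int, probs: tuple[float, ...], what: str
) -> np.ndarray:
    """Multinomial sizes; redraw (warning) if any cluster comes up empty."""
    for attempt in range(100):
        sizes = rng.multinomial(n, probs)
        if (sizes > 0).all():
            if attempt:
                logger.warning("redrew %s cluster sizes %d time(s)", what, attempt)
            return sizes
    raise RuntimeError(f"could not draw non-empty {what} cluster sizes in 100 attempts")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under ``config`` (fully reproducible given its seed)."""
    rng = np.random.default_rng(config.seed)
    gene_sizes = _cluster_sizes(rng, config.n_genes, config.gene_cluster_probs, "gene")
    go_sizes = _cluster_sizes(rng, config.n_go, config.go_cluster_probs, "GO")
    gene_labels = np.repeat(np.arange(1, config.K + 1), gene_sizes)
    go_labels = np.repeat(np.arange(1, config.L + 1), go_sizes)

    lo, hi = config.signal_alpha_range
    alpha_own = rng.uniform(lo, hi, size=config.n_genes)
    slo, shi = config.shared_alpha_range
    alpha_shared = rng.uniform(slo, shi, size=config.n_genes)

    P = rng.uniform(0.0, 1.0, size=(config.n_genes, config.n_go))
    for l in range(1, config.L + 1):
        cols = go_labels == l
        if l in config.shared_go_clusters:
            # shared signal: every gene, with its own shared-range shape
            a = alpha_shared[:, None]
            P[:, cols] = rng.beta(np.broadcast_to(a, (config.n_genes, cols.sum())), 1.0)
        elif l in config.go_owner:
            k = config.go_owner[l]
            rows = gene_labels == k
            a = alpha_own[rows][:, None]
            P[np.ix_(rows, cols)] = rng.beta(
                np.broadcast_to(a, (int(rows.sum()), int(cols.sum()))), 1.0
            )

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    go_ids = [f"GO{j + 1:04d}" for j in range(config.n_go)]
    Pmat = AssociationPValueMatrix(values=P, gene_ids=gene_ids, go_ids=go_ids)
    X = BinaryAssociationMatrix(
        values=(P < config.cutoff).astype(np.int8), gene_ids=gene_ids, go_ids=go_ids
    )

    assignments: dict[str, int] = {}
    for k in range(1, config.K + 1):
        members = np.flatnonzero(gene_labels == k)
        m = int(np.floor(config.constraint_fraction * members.size))
        chosen = rng.choice(members, size=m, replace=False)
        for i in chosen:
            assignments[gene_ids[i]] = k
    constraints = ConstraintSet(assignments=assignments, n_clusters=config.K)

    return SimulatedDataset(
        X=X,
        P=Pmat,
        true_gene_labels=gene_labels,
        true_go_labels=go_labels,
        constraints=constraints,
        per_gene_alpha=alpha_own,
    )


def default_two_cluster_config(
    snr: str = "strong", seed: int | None = None, **overrides
) -> SimulationConfig:
    """The two-pathway study condition: 100 genes in 2 clusters
    (Multinomial(100, (.5,.5))), 100 GO terms in 3 clusters
    (Multinomial(100, (.4,.4,.2))) with the third cluster shared, cutoff 0.1,
    half the genes of each cluster constrained. ``snr`` picks the signal
    shape range: strong U(0.2,0.5), weak U(0.4,0.8), mid U(0.3,0.7).
    """
    ranges = {"strong": (0.2, 0.5), "weak": (0.4, 0.8), "mid": (0.3, 0.7)}
    if snr not in ranges:
        raise ValueError(f"snr must be one of {sorted(ranges)}")
    cfg = dict(
        n_genes=100,
        n_go=100,
        K=2,
        L=3,
        gene_cluster_probs=(0.5, 0.5),
        go_cluster_probs=(0.4, 0.4, 0.2),
        signal_alpha_range=ranges[snr],
        shared_alpha_range=(0.0, 1.0),
        shared_go_clusters=frozenset({3}),
        cutoff=0.1,
        constraint_fraction=0.5,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def default_three_cluster_config(
    snr: str = "strong", seed: int | None = None, **overrides
) -> SimulationConfig:
    """The three-pathway condition: 200 genes in 3 equal clusters, 100 GO
    terms in 4 equal clusters with the fourth shared across all gene
    clusters; same SNR ranges, cutoff and constraint rule as the
    two-cluster condition.
    """
    ranges = {"strong": (0.2, 0.5), "weak": (0.4, 0.8), "mid": (0.3, 0.7)}
    if snr not in ranges:
        raise ValueError(f"snr must be one of {sorted(ranges)}")
    cfg = dict(
        n_genes=200,
        n_go=100,
        K=3,
        L=4,
        gene_cluster_probs=(1 / 3, 1 / 3, 1 / 3),
        go_cluster_probs=(0.25, 0.25, 0.25, 0.25),
        signal_alpha_range=ranges[snr],
        shared_alpha_range=(0.0, 1.0),
        shared_go_clusters=frozenset({4}),
        cutoff=0.1,
        constraint_fraction=0.5,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
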