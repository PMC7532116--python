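"""Core data containers for the constrained latent block model.

The central object is a binary gene-by-GO-term association matrix ``X``
(rows = genes, columns = GO terms), typically produced by thresholding a
literature-mining p-value matrix. Genes and GO terms each carry a latent
cluster label; every (gene-cluster, GO-cluster) block shares a single
Bernoulli rate ``theta[k, l]``. A subset of genes with known pathway
membership enters as hard ("force-in") constraints.

Cluster labels are 1-based throughout (k = 1..K for genes, l = 1..L for
GO terms), matching the convention used in all on-disk files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bernoulli rates are clipped into [EPS, 1-EPS] so that log-likelihoods of
#: all-zero / all-one blocks stay finite.
EPS = 1e-6


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class BinaryAssociationMatrix:
    """An n x p {0,1} matrix of gene-GO-term associations."""

    values: np.ndarray
    gene_ids: list[str]
    go_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("matrix must be 2-dimensional and non-empty")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"matrix entries must be 0 or 1; offending entry at "
                f"row {self.gene_ids[bad[0]]!r}, column {self.go_ids[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)
        n, p = self.values.shape
        if len(self.gene_ids) != n or len(self.go_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.go_ids, "GO id")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_go(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationPValueMatrix:
    """An n x p matrix of gene-GO-term association p-values in [0, 1]."""

    values: np.ndarray
    gene_ids: list[str]
    go_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("matrix must be 2-dimensional and non-empty")
        if not ((self.values >= 0) & (self.values <= 1)).all():
            raise ValueError("p-values must lie in [0, 1]")
        n, p = self.values.shape
        if len(self.gene_ids) != n or len(self.go_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.go_ids, "GO id")


@dataclass
class ConstraintSet:
    """Partial map gene_id -> anchored cluster label in 1..K.

    Encodes prior pathway knowledge: a constrained gene's membership is
    fixed ("forced in") for the whole fit.
    """

    assignments: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for g, k in self.assignments.items():
            if not (1 <= int(k) <= self.n_clusters):
                raise ValueError(
                    f"constraint label {k} for gene {g!r} outside 1..{self.n_clusters}"
                )
        self.assignments = {g: int(k) for g, k in self.assignments.items()}

    def label_vector(self, gene_ids: list[str]) -> np.ndarray:
        """Length-n int vector: constrained label in 1..K, 0 if unconstrained.

        Raises if a constrained gene is absent from ``gene_ids``.
        """
        index = {g: i for i, g in enumerate(gene_ids)}
        out = np.zeros(len(gene_ids), dtype=np.int64)
        for g, k in self.assignments.items():
            if g not in index:
                raise ValueError(f"constrained gene {g!r} not present in matrix")
            out[index[g]] = k
        return out

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class CoClusterModel:
    """Block parameters: theta (K x L Bernoulli rates), alpha (K), beta (L)."""

    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be K x L")
        K, L = self.theta.shape
        if self.alpha.shape != (K,) or self.beta.shape != (L,):
            raise ValueError("alpha/beta shapes inconsistent with theta")
        if np.isnan(self.theta).any() or np.isnan(self.alpha).any() or np.isnan(self.beta).any():
            raise ValueError("model contains NaN")
        if (self.theta < EPS - 1e-12).any() or (self.theta > 1 - EPS + 1e-12).any():
            raise ValueError(f"theta entries must lie in [{EPS}, {1 - EPS}]")
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if (v <= 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be positive and sum to 1")

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    @property
    def L(self) -> int:
        return self.theta.shape[1]


@dataclass
class HardAssignment:
    """Hard cluster labels after argmax: genes over 1..K, GO terms over 1..L."""

    gene_labels: np.ndarray
    go_labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_labels = np.asarray(self.gene_labels, dtype=np.int64)
        self.go_labels = np.asarray(self.go_labels, dtype=np.int64)
        if (self.gene_labels < 1).any() or (self.go_labels < 1).any():
            raise ValueError("labels must be >= 1")


@dataclass
class FitResult:
    """Everything the alternating fit returns."""

    model: CoClusterModel
    assignment: HardAssignment
    gene_responsibilities: np.ndarray
    go_responsibilities: np.ndarray
    n_outer_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class BootstrapResult:
    """Majority-voted gene labels with per-gene assignment probabilities."""

    voted_labels: np.ndarray
    probabilities: np.ndarray
    B: int
    per_replicate_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voted_labels = np.asarray(self.voted_labels, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
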