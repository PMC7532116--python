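"""The two conditional Bernoulli-mixture EM algorithms.

The latent block model is fitted by a divide-and-conquer alternation: given
hard GO-term cluster labels, each gene's row collapses to a vector of
per-GO-cluster one-counts ``y[i, l]`` (out of cluster sizes ``n_l``) and the
genes follow a K-component product-binomial mixture; symmetrically, given
hard gene labels, GO terms follow an L-component mixture over ``u[j, k]``
counts. Both mixtures share the block rate matrix ``theta``.

Prior pathway knowledge enters the gene side only, as hard "force-in"
constraints: a constrained gene's responsibility row is pinned to its known
cluster at every E-step, which in turn shapes the M-step estimate of that
cluster's block rates and thereby steers the assignment of the free genes.

Each EM monitors the observed-data log-likelihood (constrained genes
contribute the log-density of their forced component); this quantity is
non-decreasing across E+M sweeps. The classification-style complete
log-likelihoods are exposed separately (:func:`gene_complete_loglik`,
:func:`go_complete_loglik`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .types import EPS, BinaryAssociationMatrix, CoClusterModel, ConstraintSet

logger = logging.getLogger(__name__)

#: floor for mixing weights inside log(); lets clusters die without -inf
_W_FLOOR = 1e-300


@dataclass
class GeneBlockCounts:
    """Per-gene one-counts within each GO cluster: y[i,l], sizes n_l."""

    y: np.ndarray
    n_l: np.ndarray


@dataclass
class GoBlockCounts:
    """Per-GO-term one-counts within each gene cluster: u[j,k], sizes p_k."""

    u: np.ndarray
    p_k: np.ndarray


def _indicator(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """One-hot matrix from 1-based labels."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 1 or labels.max() > n_clusters:
        raise ValueError(f"labels must lie in 1..{n_clusters}")
    return np.eye(n_clusters, dtype=np.int64)[labels - 1]


# --------------------------------------------------------------------------
# gene side: mixture over genes given GO-term labels
# --------------------------------------------------------------------------

def compute_gene_counts(
    X: BinaryAssociationMatrix | np.ndarray,
    go_labels: np.ndarray,
    L: int | None = None,
) -> GeneBlockCounts:
    """Collapse each gene's row to per-GO-cluster one-counts.

    y[i, l] = sum_j x[i, j] 1{z_j = l};  n_l = |{j : z_j = l}|.
    """
    Xv = X.values if isinstance(X, BinaryAssociationMatrix) else np.asarray(X)
    go_labels = np.asarray(go_labels, dtype=np.int64)
    if L is None:
        L = int(go_labels.max())
    Z = _indicator(go_labels, L)
    n_l = Z.sum(axis=0)
    if (n_l == 0).any():
        empty = np.where(n_l == 0)[0] + 1
        logger.warning("empty GO cluster(s) %s in counts", list(empty))
    return GeneBlockCounts(y=Xv @ Z, n_l=n_l)


def _gene_log_joint(counts: GeneBlockCounts, model: CoClusterModel) -> np.ndarray:
    """log( alpha_k * prod_l theta^y (1-theta)^(n-y) ), shape (n, K)."""
    lt = np.log(model.theta)
    l1t = np.log1p(-model.theta)
    log_alpha = np.log(np.maximum(model.alpha, _W_FLOOR))
    return (
        log_alpha[None, :]
        + counts.y @ lt.T
        + (counts.n_l[None, :] - counts.y) @ l1t.T
    )


def gene_e_step(
    counts: GeneBlockCounts,
    model: CoClusterModel,
    constraints: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior gene-cluster responsibilities, with force-in rows one-hot.

    ``constraints`` is a length-n vector with the anchored label in 1..K or
    0 for free genes (see :meth:`ConstraintSet.label_vector`).
    """
    lj = _gene_log_joint(counts, model)
    resp = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
    if constraints is not None:
        fixed = constraints > 0
        if fixed.any():
            resp[fixed] = 0.0
            resp[fixed, constraints[fixed] - 1] = 1.0
    return resp


def gene_m_step(
    counts: GeneBlockCounts, resp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """theta[k,l] = sum_i y[i,l] w[i,k] / (n_l sum_i w[i,k]); alpha = mean w."""
    n = resp.shape[0]
    wk = resp.sum(axis=0)
    denom = counts.n_l[None, :] * wk[:, None]
    if (denom <= 0).any():
        logger.warning("degenerate M-step denominator (dead cluster or empty GO cluster)")
    theta = (resp.T @ counts.y) / np.maximum(denom, EPS)
    theta = np.clip(theta, EPS, 1 - EPS)
    alpha = wk / n
    return theta, alpha


def gene_complete_loglik(
    counts: GeneBlockCounts, resp: np.ndarray, model: CoClusterModel
) -> float:
    """Classification-style complete log-likelihood for the gene mixture:
    sum_i sum_k w_ik ( ln a_k + sum_l y_il ln theta_kl + (n_l - y_il) ln(1-theta_kl) ).
    """
    return float(np.sum(resp * _gene_log_joint(counts, model)))


def _gene_observed_loglik(
    counts: GeneBlockCounts,
    model: CoClusterModel,
    constraints: np.ndarray | None,
) -> float:
    """Mixture log-likelihood; constrained genes contribute their forced term."""
    lj = _gene_log_joint(counts, model)
    per_gene = logsumexp(lj, axis=1)
    if constraints is not None:
        fixed = constraints > 0
        per_gene[fixed] = lj[fixed, constraints[fixed] - 1]
    return float(per_gene.sum())


def run_gene_em(
    X: BinaryAssociationMatrix | np.ndarray,
    go_labels: np.ndarray,
    init_model: CoClusterModel,
    constraints: ConstraintSet | np.ndarray | None = None,
    tol: float = 1e-6,
    max_inner: int = 200,
) -> tuple[CoClusterModel, np.ndarray, np.ndarray, list[float]]:
    """Run the constrained gene-side EM to convergence.

    Returns ``(model, responsibilities, gene_labels, loglik_trace)`` where
    gene_labels are the per-row argmax (ties -> lowest index) and constrained
    genes keep their forced label. Convergence: relative change of the
    observed-data log-likelihood below ``tol``, or ``max_inner`` sweeps.
    """
    cvec = _constraint_vector(X, constraints, init_model.K)
    counts = compute_gene_counts(X, go_labels, init_model.L)
    model = init_model
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_inner):
        resp = gene_e_step(counts, model, cvec)
        theta, alpha = gene_m_step(counts, resp)
        model = CoClusterModel(theta=theta, alpha=_safe_simplex(alpha), beta=model.beta)
        ll = _gene_observed_loglik(counts, model, cvec)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite gene log-likelihood: {ll}")
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) / (abs(prev) + 1.0) < tol:
            break
        prev = ll
    resp = gene_e_step(counts, model, cvec)
    labels = np.argmax(resp, axis=1) + 1
    if cvec is not None:
        fixed = cvec > 0
        labels[fixed] = cvec[fixed]
    return model, resp, labels, trace


# --------------------------------------------------------------------------
# GO-term side: mixture over columns given gene labels (no constraints)
# --------------------------------------------------------------------------

def compute_go_counts(
    X: BinaryAssociationMatrix | np.ndarray,
    gene_labels: np.ndarray,
    K: int | None = None,
) -> GoBlockCounts:
    """u[j, k] = sum_i x[i, j] 1{w_i = k};  p_k = |{i : w_i = k}|."""
    Xv = X.values if isinstance(X, BinaryAssociationMatrix) else np.asarray(X)
    gene_labels = np.asarray(gene_labels, dtype=np.int64)
    if K is None:
        K = int(gene_labels.max())
    W = _indicator(gene_labels, K)
    p_k = W.sum(axis=0)
    if (p_k == 0).any():
        empty = np.where(p_k == 0)[0] + 1
        logger.warning("empty gene cluster(s) %s in counts", list(empty))
    return GoBlockCounts(u=Xv.T @ W, p_k=p_k)


def _go_log_joint(counts: GoBlockCounts, model: CoClusterModel) -> np.ndarray:
    """log( beta_l * prod_k theta^u (1-theta)^(p_k-u) ), shape (p, L)."""
    lt = np.log(model.theta)
    l1t = np.log1p(-model.theta)
    log_beta = np.log(np.maximum(model.beta, _W_FLOOR))
    return (
        log_beta[None, :]
        + counts.u @ lt
        + (counts.p_k[None, :] - counts.u) @ l1t
    )


def go_e_step(counts: GoBlockCounts, model: CoClusterModel) -> np.ndarray:
    """Posterior GO-cluster responsibilities (no constraints on this side)."""
    lj = _go_log_joint(counts, model)
    return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))


def go_m_step(counts: GoBlockCounts, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """theta[k,l] = sum_j u[j,k] z[j,l] / (p_k sum_j z[j,l]); beta = mean z."""
    p = resp.shape[0]
    zl = resp.sum(axis=0)
    denom = counts.p_k[:, None] * zl[None, :]
    if (denom <= 0).any():
        logger.warning("degenerate M-step denominator (dead cluster or empty gene cluster)")
    theta = (counts.u.T @ resp) / np.maximum(denom, EPS)
    theta = np.clip(theta, EPS, 1 - EPS)
    beta = zl / p
    return theta, beta


def go_complete_loglik(
    counts: GoBlockCounts, resp: np.ndarray, model: CoClusterModel
) -> float:
    """sum_j sum_l z_jl ( ln b_l + sum_k u_jk ln theta_kl + (p_k - u_jk) ln(1-theta_kl) )."""
    return float(np.sum(resp * _go_log_joint(counts, model)))


def _go_observed_loglik(counts: GoBlockCounts, model: CoClusterModel) -> float:
    return float(logsumexp(_go_log_joint(counts, model), axis=1).sum())


def run_go_em(
    X: BinaryAssociationMatrix | np.ndarray,
    gene_labels: np.ndarray,
    init_model: CoClusterModel,
    tol: float = 1e-6,
    max_inner: int = 200,
) -> tuple[CoClusterModel, np.ndarray, np.ndarray, list[float]]:
    """GO-side EM: exact mirror of :func:`run_gene_em` without constraints."""
    counts = compute_go_counts(X, gene_labels, init_model.K)
    model = init_model
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_inner):
        resp = go_e_step(counts, model)
        theta, beta = go_m_step(counts, resp)
        model = CoClusterModel(theta=theta, alpha=model.alpha, beta=_safe_simplex(beta))
        ll = _go_observed_loglik(counts, model)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite GO log-likelihood: {ll}")
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) / (abs(prev) + 1.0) < tol:
            break
        prev = ll
    resp = go_e_step(counts, model)
    labels = np.argmax(resp, axis=1) + 1
    return model, resp, labels, trace


# --------------------------------------------------------------------------

def _safe_simplex(w: np.ndarray) -> np.ndarray:
    """Nudge dead components off zero so the simplex invariant holds."""
    if (w <= 0).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = np.maximum(w, 1e-12)
            w = w / w.sum()
    return w


def _constraint_vector(
    X: BinaryAssociationMatrix | np.ndarray,
    constraints: ConstraintSet | np.ndarray | None,
    K: int,
) -> np.ndarray | None:
    if constraints is None:
        return None
    if isinstance(constraints, ConstraintSet):
        if not isinstance(X, BinaryAssociationMatrix):
            raise TypeError("a ConstraintSet needs a BinaryAssociationMatrix to resolve ids")
        if constraints.n_clusters != K:
            raise ValueError("ConstraintSet.n_clusters disagrees with model K")
        return constraints.label_vector(X.gene_ids)
    vec = np.asarray(constraints, dtype=np.int64)
    if (vec < 0).any() or (vec > K).any():
        raise ValueError(f"constraint labels must lie in 0..{K} (0 = free)")
    return vec
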