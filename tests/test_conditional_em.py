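"""Unit and property tests for the two conditional EM algorithms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from palmer import (
    CoClusterModel,
    compute_gene_counts,
    compute_go_counts,
    gene_complete_loglik,
    gene_e_step,
    gene_m_step,
    go_e_step,
    run_gene_em,
    run_go_em,
)
from palmer.types import EPS


def make_model(theta, alpha=None, beta=None):
    theta = np.clip(np.asarray(theta, dtype=float), EPS, 1 - EPS)
    K, L = theta.shape
    return CoClusterModel(
        theta=theta,
        alpha=np.full(K, 1 / K) if alpha is None else np.asarray(alpha),
        beta=np.full(L, 1 / L) if beta is None else np.asarray(beta),
    )


class TestCounts:
    def test_hand_counted_gene_side(self):
        counts = compute_gene_counts(np.array([[1, 1], [0, 0]]), np.array([1, 1]))
        np.testing.assert_array_equal(counts.y, [[2], [0]])
        np.testing.assert_array_equal(counts.n_l, [2])

    def test_all_zero_matrix(self):
        counts = compute_gene_counts(np.zeros((3, 4)), np.array([1, 1, 2, 2]))
        assert not counts.y.any()

    def test_hand_counted_go_side(self):
        counts = compute_go_counts(np.array([[1, 0], [1, 0]]), np.array([1, 1]))
        np.testing.assert_array_equal(counts.u, [[2], [0]])
        np.testing.assert_array_equal(counts.p_k, [2])

    def test_all_ones_go_side(self):
        counts = compute_go_counts(np.ones((4, 3)), np.array([1, 2, 1, 2]))
        np.testing.assert_array_equal(counts.u, np.full((3, 2), 2))

    @given(
        X=arrays(np.int8, (5, 4), elements=st.integers(0, 1)),
        labels=arrays(np.int64, 4, elements=st.integers(1, 2)),
    )
    def test_counts_match_brute_force_double_loop(self, X, labels):
        L = 2
        counts = compute_gene_counts(X, labels, L)
        for i in range(5):
            for l in range(1, L + 1):
                expected = sum(X[i, j] for j in range(4) if labels[j] == l)
                assert counts.y[i, l - 1] == expected
        gcounts = compute_go_counts(X.T, labels, L)
        np.testing.assert_array_equal(gcounts.u, counts.y)


class TestGeneEStep:
    def test_identical_theta_rows_give_prior_posterior(self):
        model = make_model([[0.3, 0.6], [0.3, 0.6]], alpha=[0.5, 0.5])
        counts = compute_gene_counts(
            np.array([[1, 0, 1], [0, 1, 1]]), np.array([1, 1, 2])
        )
        resp = gene_e_step(counts, model)
        np.testing.assert_allclose(resp, 0.5)

    def test_force_in_overrides_data(self):
        model = make_model([[0.99], [0.01]], alpha=[0.5, 0.5])
        counts = compute_gene_counts(np.array([[1, 1, 1]]), np.array([1, 1, 1]))
        resp = gene_e_step(counts, model, constraints=np.array([2]))
        np.testing.assert_array_equal(resp, [[0.0, 1.0]])

    def test_two_component_bayes_arithmetic(self):
        # alpha=(.5,.5), theta=(.9,.1), y=2 of n=2:
        # w_1 = .5*.81 / (.5*.81 + .5*.01) = .405/.410
        model = make_model([[0.9], [0.1]], alpha=[0.5, 0.5])
        counts = compute_gene_counts(np.array([[1, 1]]), np.array([1, 1]))
        resp = gene_e_step(counts, model)
        np.testing.assert_allclose(resp[0, 0], 0.405 / 0.410, rtol=1e-12)

    def test_rows_sum_to_one(self, rng):
        model = make_model(rng.uniform(0.1, 0.9, (3, 2)), alpha=[0.2, 0.3, 0.5])
        X = rng.integers(0, 2, (10, 6))
        counts = compute_gene_counts(X, np.array([1, 1, 1, 2, 2, 2]))
        resp = gene_e_step(counts, model, constraints=np.array([1] + [0] * 9))
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)


class TestGeneMStep:
    def test_single_block_theta_is_matrix_mean(self):
        counts = compute_gene_counts(np.array([[1], [0]]), np.array([1]))
        theta, alpha = gene_m_step(counts, np.array([[1.0], [1.0]]))
        assert theta[0, 0] == pytest.approx(0.5)
        assert alpha[0] == pytest.approx(1.0)

    def test_all_ones_clips_at_boundary(self):
        counts = compute_gene_counts(np.ones((2, 3)), np.array([1, 1, 1]))
        theta, _ = gene_m_step(counts, np.ones((2, 1)))
        assert theta[0, 0] == 1 - EPS

    def test_theta_matches_brute_force_weighted_ratio(self, rng):
        X = rng.integers(0, 2, (6, 5))
        go_labels = np.array([1, 2, 1, 2, 2])
        resp = rng.dirichlet(np.ones(2), size=6)
        counts = compute_gene_counts(X, go_labels)
        theta, alpha = gene_m_step(counts, resp)
        for k in range(2):
            for l in range(2):
                num = sum(counts.y[i, l] * resp[i, k] for i in range(6))
                den = counts.n_l[l] * resp[:, k].sum()
                assert theta[k, l] == pytest.approx(num / den)
        np.testing.assert_allclose(alpha, resp.mean(axis=0))


class TestCompleteLoglik:
    def test_uniform_half_theta_closed_form(self):
        # one component, theta=.5: every one of the 2*3 cells contributes ln .5
        model = make_model([[0.5]], alpha=[1.0])
        counts = compute_gene_counts(
            np.array([[1, 0, 1], [0, 0, 1]]), np.array([1, 1, 1])
        )
        ll = gene_complete_loglik(counts, np.ones((2, 1)), model)
        assert ll == pytest.approx(6 * np.log(0.5))

    def test_hard_assignment_equals_per_cell_bernoulli_sum(self, rng):
        X = rng.integers(0, 2, (5, 6))
        go_labels = np.array([1, 1, 2, 2, 2, 1])
        gene_labels = np.array([1, 2, 1, 2, 1])
        model = make_model(rng.uniform(0.2, 0.8, (2, 2)), alpha=[0.4, 0.6])
        resp = np.eye(2)[gene_labels - 1]
        counts = compute_gene_counts(X, go_labels)
        expected = 0.0
        for i in range(5):
            expected += np.log(model.alpha[gene_labels[i] - 1])
            for j in range(6):
                th = model.theta[gene_labels[i] - 1, go_labels[j] - 1]
                expected += np.log(th) if X[i, j] else np.log(1 - th)
        assert gene_complete_loglik(counts, resp, model) == pytest.approx(expected)


class TestRunGeneEm:
    def test_separable_blocks_recovered_with_half_constraints(self, block_matrix):
        model = make_model([[0.9, 0.1], [0.1, 0.9]])
        cons = np.array([1, 0, 0, 2, 0, 0])
        _, _, labels, _ = run_gene_em(
            block_matrix.values, np.array([1, 1, 2, 2]), model, cons
        )
        np.testing.assert_array_equal(labels, [1, 1, 1, 2, 2, 2])

    def test_loglik_trace_monotone(self, rng):
        X = rng.integers(0, 2, (20, 10))
        model = make_model(rng.uniform(0.2, 0.8, (2, 2)))
        _, _, _, trace = run_gene_em(
            X, rng.integers(1, 3, 10), model, np.array([1, 2] + [0] * 18)
        )
        assert all(b - a >= -1e-8 for a, b in zip(trace, trace[1:]))

    def test_converged_labels_are_single_flip_optimal(self, rng):
        """No single unconstrained gene relabeling increases the complete
        log-likelihood at the converged model (exhaustive flip oracle)."""
        X = rng.integers(0, 2, (6, 4))
        go_labels = np.array([1, 1, 2, 2])
        cons = np.array([1, 2, 0, 0, 0, 0])
        model = make_model(rng.uniform(0.2, 0.8, (2, 2)))
        model, resp, labels, _ = run_gene_em(X, go_labels, model, cons)
        counts = compute_gene_counts(X, go_labels)
        base = gene_complete_loglik(counts, np.eye(2)[labels - 1], model)
        for i in range(6):
            if cons[i]:
                continue
            for k in (1, 2):
                if k == labels[i]:
                    continue
                flipped = labels.copy()
                flipped[i] = k
                ll = gene_complete_loglik(counts, np.eye(2)[flipped - 1], model)
                assert ll <= base + 1e-9

    def test_force_in_persists_through_iterations(self, rng):
        X = rng.integers(0, 2, (15, 8))
        cons = np.array([2, 1] * 3 + [0] * 9)
        model = make_model(rng.uniform(0.2, 0.8, (2, 3)))
        _, resp, labels, _ = run_gene_em(X, rng.integers(1, 4, 8), model, cons)
        fixed = cons > 0
        np.testing.assert_array_equal(labels[fixed], cons[fixed])
        np.testing.assert_array_equal(
            resp[fixed], np.eye(2)[cons[fixed] - 1]
        )


class TestGoSide:
    def test_symmetric_theta_posterior_equals_prior(self):
        # identical theta columns across l: the data cannot distinguish the
        # GO components, so the posterior falls back to the prior beta
        model = make_model(
            [[0.4, 0.4], [0.7, 0.7]], alpha=[0.5, 0.5], beta=np.array([0.3, 0.7])
        )
        counts = compute_go_counts(np.array([[1, 1], [0, 1]]), np.array([1, 2]))
        resp = go_e_step(counts, model)
        np.testing.assert_allclose(resp, [[0.3, 0.7], [0.3, 0.7]], rtol=1e-9)

    def test_single_gene_cluster_reduces_to_1d_bernoulli_mixture(self):
        # K=1: column j has u_j ones of p_1=2; posterior over L=2 components
        # is Bayes on Binomial(2, theta_l) with prior beta
        model = make_model(
            np.array([[0.8, 0.2]]), alpha=np.array([1.0]), beta=np.array([0.3, 0.7])
        )
        X = np.array([[1, 0], [1, 0]])
        counts = compute_go_counts(X, np.array([1, 1]))
        resp = go_e_step(counts, model)
        for j, u in enumerate([2, 0]):
            post = np.array(
                [
                    b * t**u * (1 - t) ** (2 - u)
                    for b, t in zip(model.beta, model.theta[0])
                ]
            )
            np.testing.assert_allclose(resp[j], post / post.sum(), rtol=1e-9)

    def test_transpose_duality_with_unconstrained_gene_em(self, rng):
        """GO-side EM on X equals the unconstrained gene-side EM on X.T with
        all roles swapped (K<->L, alpha<->beta, y<->u)."""
        X = rng.integers(0, 2, (12, 9))
        gene_labels = rng.integers(1, 3, 12)
        theta = rng.uniform(0.2, 0.8, (2, 3))
        model = make_model(theta, alpha=[0.5, 0.5], beta=[0.2, 0.3, 0.5])
        go_model, go_resp, go_labels, go_trace = run_go_em(X, gene_labels, model)

        swapped = CoClusterModel(theta=theta.T, alpha=model.beta, beta=model.alpha)
        g_model, g_resp, g_labels, g_trace = run_gene_em(
            X.T, gene_labels, swapped, constraints=None
        )
        np.testing.assert_allclose(g_model.theta, go_model.theta.T, atol=1e-12)
        np.testing.assert_allclose(g_model.alpha, go_model.beta, atol=1e-12)
        np.testing.assert_allclose(g_resp, go_resp, atol=1e-12)
        np.testing.assert_array_equal(g_labels, go_labels)
        np.testing.assert_allclose(g_trace, go_trace, atol=1e-9)
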