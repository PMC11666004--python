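"""Largest-K norm machinery and the DC solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardggm import (
    DCConfig,
    SolverConfig,
    dc_estimate,
    dc_objective,
    find_eta,
    l0_norm,
    largest_k_norm,
    neg_log_likelihood,
    subgradient_matrix,
    surrogate_objective,
    topk_subgradient,
)
from conftest import random_pd


class TestVectorNorms:
    @pytest.mark.parametrize(
        "w,expected",
        [([1, 0, 2], 2), ([0, 0, 0], 0), ([1, -1, 2, 3], 4)],
    )
    def test_l0(self, w, expected):
        assert l0_norm(np.array(w, float)) == expected

    def test_largest_k_examples(self):
        assert largest_k_norm(np.array([3.0, -1.0, 2.0]), 2) == pytest.approx(5.0)
        w = np.array([0.3, -2.0, 1.1])
        assert largest_k_norm(w, 3) == pytest.approx(np.abs(w).sum())

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            largest_k_norm(np.ones(3), 0)
        with pytest.raises(ValueError):
            largest_k_norm(np.ones(3), 4)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_l1_gap_zero_iff_sparse(self, data):
        """||w||_1 - |||w|||_K = 0 exactly when at most K entries are nonzero."""
        m = data.draw(st.integers(2, 8))
        support = data.draw(st.integers(0, m))
        K = data.draw(st.integers(1, m))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        w = np.zeros(m)
        idx = rng.choice(m, size=support, replace=False)
        w[idx] = rng.uniform(0.5, 2.0, support) * rng.choice([-1, 1], support)
        gap = np.abs(w).sum() - largest_k_norm(w, K)
        assert gap >= -1e-12
        assert (abs(gap) < 1e-12) == (l0_norm(w) <= K)

    def test_subgradient_examples(self):
        assert np.array_equal(topk_subgradient(np.array([3.0, -1.0, 2.0]), 2), [1, 0, 1])
        # lowest-index tie break
        assert np.array_equal(topk_subgradient(np.array([1.0, -1.0]), 1), [1, 0])

    def test_subgradient_identity(self):
        """s(w)'w equals the largest-K norm (support function identity)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(2, 12))
            K = int(rng.integers(1, m + 1))
            w = rng.standard_normal(m)
            s = topk_subgradient(w, K)
            assert s @ w == pytest.approx(largest_k_norm(w, K), abs=1e-12)


class TestSubgradientMatrix:
    def test_identity_matrix(self):
        for K in (4, 7, 16):
            V = subgradient_matrix(np.eye(4), K)
            assert np.array_equal(V, np.eye(4))

    def test_dominant_pair_selected(self):
        p = 4
        Om = np.eye(p)
        Om[0, 1] = Om[1, 0] = -0.9
        V = subgradient_matrix(Om, p + 2)
        expected = np.eye(p)
        expected[0, 1] = expected[1, 0] = -1.0
        assert np.array_equal(V, expected)

    def test_properties_random(self):
        """Symmetry, unit diagonal, at most K nonzeros, on 100 random draws."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = int(rng.integers(3, 9))
            A = rng.standard_normal((p, p))
            Om = 0.5 * (A + A.T)
            np.fill_diagonal(Om, np.abs(np.diag(Om)) + 0.5)
            K = int(rng.integers(p, p * p + 1))
            V = subgradient_matrix(Om, K)
            assert np.array_equal(V, V.T)
            assert np.all(np.diag(V) == 1)
            assert np.count_nonzero(V) <= K
            assert set(np.unique(V)).issubset({-1.0, 0.0, 1.0})

    def test_matches_vector_rule_diagonal_first(self, rng):
        """With distinct magnitudes, pairwise selection equals the vector
        top-K applied off-diagonal after the diagonal is taken."""
        p = 5
        A = rng.standard_normal((p, p))
        Om = 0.5 * (A + A.T)
        np.fill_diagonal(Om, np.abs(np.diag(Om)) + 1.0)
        K = p + 6
        V = subgradient_matrix(Om, K)
        iu = np.triu_indices(p, 1)
        order = np.argsort(-np.abs(Om[iu]))
        chosen = set(zip(iu[0][order[:3]], iu[1][order[:3]]))
        for j, k in zip(*iu):
            expect = np.sign(Om[j, k]) if (j, k) in chosen else 0.0
            assert V[j, k] == expect

    def test_nonpositive_diagonal_rejected(self):
        Om = np.eye(3)
        Om[1, 1] = 0.0
        with pytest.raises(ValueError, match="diagonal"):
            subgradient_matrix(Om, 5)


class TestFindEta:
    @pytest.mark.parametrize("alpha,expected_eta", [(0.5, 0.5), (0.9, 0.9)])
    def test_identity_case(self, alpha, expected_eta):
        eta, n_eig = find_eta(np.eye(3), np.eye(3), alpha)
        assert eta == pytest.approx(expected_eta)
        assert n_eig == 2

    def test_eta_bounds_random(self, rng):
        """Accepted eta lies in (0, alpha*lambda_min(S)] and keeps S - eta V
        positive definite."""
        for _ in range(20):
            p = int(rng.integers(3, 9))
            S = random_pd(rng, p)
            A = rng.standard_normal((p, p))
            Om = 0.5 * (A + A.T)
            np.fill_diagonal(Om, 1.0)
            V = subgradient_matrix(Om, int(rng.integers(p, p * p + 1)))
            eta, n_eig = find_eta(S, V, 0.5)
            lam_min = np.linalg.eigvalsh(S)[0]
            assert 0 < eta <= 0.5 * lam_min + 1e-15
            assert np.linalg.eigvalsh(S - eta * V)[0] > 0
            assert n_eig >= 2

    def test_singular_s_raises_shrinkage_hint(self, rng):
        X = rng.standard_normal((3, 6))  # n < p: singular
        S = X.T @ X / 3
        with pytest.raises(ValueError, match="shrinkage"):
            find_eta(S, np.eye(6), 0.5)


class TestDCObjectives:
    def test_penalty_vanishes_when_sparse_enough(self):
        assert dc_objective(np.eye(3), np.eye(3), 9, 5.0) == pytest.approx(3.0)
        assert dc_objective(np.eye(3), np.eye(3), 3, 5.0) == pytest.approx(3.0)

    def test_penalty_is_sum_of_smallest_entries(self, rng):
        S = random_pd(rng, 3)
        Om = np.linalg.inv(S)  # dense
        eta = 0.7
        vals = np.sort(np.abs(Om.ravel()))
        expected = neg_log_likelihood(Om, S) + eta * vals[:5].sum()
        assert dc_objective(Om, S, 4, eta) == pytest.approx(expected, rel=1e-12)

    def test_surrogate_touches_at_incumbent(self, rng):
        """g_t(Omega_t) equals the DC objective at the incumbent (the
        subgradient is exact when the diagonal is dominant)."""
        S = random_pd(rng, 4)
        Om = np.linalg.inv(S) + 3 * np.eye(4)
        for K in (4, 8, 12):
            assert surrogate_objective(Om, S, K, 0.3, Om) == pytest.approx(
                dc_objective(Om, S, K, 0.3), rel=1e-10
            )

    def test_surrogate_majorizes(self, rng):
        """g_t(Omega) >= DC objective for Omega != Omega_t (convexity of the
        largest-K norm)."""
        S = random_pd(rng, 4)
        Om_t = np.linalg.inv(S) + 3 * np.eye(4)
        for _ in range(20):
            E = rng.standard_normal((4, 4))
            Om = Om_t + 0.3 * (E + E.T)
            if np.linalg.eigvalsh(Om)[0] <= 0:
                continue
            K = int(rng.integers(4, 17))
            assert surrogate_objective(Om, S, K, 0.3, Om_t) >= dc_objective(
                Om, S, K, 0.3
            ) - 1e-10

    def test_eta_zero_is_plain_loss(self, rng):
        S = random_pd(rng, 3)
        Om = np.linalg.inv(S)
        assert surrogate_objective(Om, S, 4, 0.0, Om) == pytest.approx(
            neg_log_likelihood(Om, S)
        )


class TestDCEstimate:
    def test_full_budget_recovers_inverse(self, rng):
        """K = p^2 leaves the problem unconstrained up to the vanishing DC
        penalty: the estimate approaches S^{-1}."""
        S = random_pd(rng, 3)
        est, trace = dc_estimate(S, 9, DCConfig(glasso_config=SolverConfig(eps=1e-12, inner_tol=1e-12)))
        assert np.abs(est.precision - np.linalg.inv(S)).max() < 5e-3

    def test_final_objective_below_initial(self, rng):
        for _ in range(5):
            S = random_pd(rng, 5)
            K = 11
            est, trace = dc_estimate(S, K)
            Om0 = np.linalg.inv(S + np.eye(5))
            eta0 = trace.records[0].eta
            assert trace.records[-1].dc_objective <= dc_objective(Om0, S, K, eta0) + 1e-8

    def test_fixed_eta_descent(self, rng):
        """While eta stays constant between outer iterations the DC objective
        does not increase (majorize-minimize descent)."""
        for _ in range(10):
            S = random_pd(rng, 6)
            _, trace = dc_estimate(S, 6 + 8)
            for prev, cur in zip(trace.records, trace.records[1:]):
                if prev.eta == cur.eta:
                    assert cur.dc_objective <= prev.dc_objective + 1e-7

    def test_pd_output_and_trace_invariants(self, rng):
        S = random_pd(rng, 6)
        est, trace = dc_estimate(S, 14)
        assert est.converged
        assert est.smallest_eigenvalue() > 0
        lam_min = np.linalg.eigvalsh(S)[0]
        for r in trace.records:
            assert 0 < r.eta < lam_min
            assert r.n_eig >= 2

    def test_matches_enumeration_oracle(self):
        """On p=4, K=8 the DC objective never exceeds the exhaustive
        support-constrained MLE optimum (the penalized problem relaxes the
        constraint); gap tolerance 1e-6."""
        from _oracles import best_support_mle

        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            S = random_pd(rng, 4)
            _, trace = dc_estimate(S, 8)
            oracle = best_support_mle(S, 2)
            gaps.append(trace.records[-1].dc_objective - oracle)
        assert max(gaps) <= 1e-6

    def test_k_out_of_range(self, rng):
        S = random_pd(rng, 4)
        with pytest.raises(ValueError):
            dc_estimate(S, 3)
        with pytest.raises(ValueError):
            dc_estimate(S, 17)
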