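import math

import numpy as np
import pytest
from scipy import sparse
from scipy.special import digamma

from hlavb.inference import (
    DirichletMultinomialVB,
    PriorConfig,
    elbo,
    run_vb,
    select_alpha0,
    vbe_step,
    vbm_step,
)

from oracles import (
    dense_to_sparse_loglik,
    fixed_point_elbo,
    fixed_point_read_counts,
    random_instance,
)


def csr(rows):
    """Dense list-of-lists with None for non-hits -> csr log-lik matrix."""
    dense = np.array([[v if v is not None else -np.inf for v in row] for row in rows])
    return dense_to_sparse_loglik(dense)


class TestVbeStep:
    def test_symmetric_read_splits_half_half(self):
        m = csr([[-1.0, -1.0]])
        resp, r = vbe_step(m, np.array([3.0, 3.0]))
        assert resp.toarray().ravel() == pytest.approx([0.5, 0.5])
        assert r == pytest.approx([0.5, 0.5])

    def test_unique_read_gets_full_responsibility(self):
        m = csr([[-2.0, None], [-1.0, -1.0]])
        resp, r = vbe_step(m, np.array([1.0, 1.0]))
        assert resp[0, 0] == pytest.approx(1.0)
        assert r[0] + r[1] == pytest.approx(2.0)

    def test_digamma_weighting_against_scalar_oracle(self):
        # equal likelihoods, alpha = (2, 1): ratio exp(psi(2)) : exp(psi(1))
        m = csr([[-1.0, -1.0]])
        resp, _ = vbe_step(m, np.array([2.0, 1.0]))
        # psi(2) = 1 - gamma, psi(1) = -gamma: ratio e^1 : 1 = 0.73106 : 0.26894
        w2, w1 = math.exp(digamma(2.0)), math.exp(digamma(1.0))
        assert resp[0, 0] == pytest.approx(w2 / (w2 + w1), abs=1e-12)
        assert resp[0, 0] == pytest.approx(0.73106, abs=5e-6)
        assert resp[0, 1] == pytest.approx(0.26894, abs=5e-6)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            vbe_step(csr([[-1.0]]), np.array([0.0]))


class TestVbmStep:
    def test_closed_form(self):
        alpha, theta = vbm_step(np.array([3.0, 1.0]), alpha0=1.0)
        assert alpha == pytest.approx([4.0, 2.0])
        assert theta == pytest.approx([2 / 3, 1 / 3])

    def test_prior_mean_with_no_reads(self):
        _, theta = vbm_step(np.zeros(2), alpha0=1.0)
        assert theta == pytest.approx([0.5, 0.5])

    def test_small_alpha0_limit_concentrates(self):
        _, theta = vbm_step(np.array([10.0, 0.0]), alpha0=1e-9)
        assert theta == pytest.approx([1.0, 0.0], abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            vbm_step(np.array([1.0]), alpha0=0.0)
        with pytest.raises(ValueError):
            vbm_step(np.array([-1.0]), alpha0=1.0)


class TestElbo:
    def test_degenerate_single_read_single_allele(self):
        m = csr([[-1.0]])
        resp = sparse.csr_matrix(np.array([[1.0]]))
        for alpha0 in (0.1, 1.0, 2.0):
            assert elbo(m, resp, np.array([alpha0 + 1.0]), alpha0) == pytest.approx(-1.0)

    def test_invariant_under_allele_relabeling(self):
        m = csr([[-1.0, None], [None, -1.0], [-2.0, -2.0]])
        state = run_vb(m, PriorConfig(alpha0=0.5, tol=1e-10, max_iter=500))
        perm = csr([[None, -1.0], [-1.0, None], [-2.0, -2.0]])
        # relabel alleles and swap the two unique reads: same instance
        state_p = run_vb(perm, PriorConfig(alpha0=0.5, tol=1e-10, max_iter=500))
        assert state.elbo == pytest.approx(state_p.elbo, abs=1e-9)
        assert sorted(state.r_hat) == pytest.approx(sorted(state_p.r_hat), abs=1e-6)


class TestRunVb:
    def test_unique_reads_converge_to_closed_form(self):
        m = csr([[-1.0, None]] * 10)
        state = run_vb(m, PriorConfig(alpha0=1.0))
        assert state.converged and state.n_iter <= 2
        assert state.r_hat == pytest.approx([10.0, 0.0])
        assert state.theta_mean == pytest.approx([11 / 12, 1 / 12])

    def test_symmetric_shared_reads_stay_at_half(self):
        rows = [[-1.0, None]] * 4 + [[None, -1.0]] * 4 + [[-2.0, -2.0]] * 4
        state = run_vb(csr(rows), PriorConfig(alpha0=1.0, tol=1e-9))
        assert state.r_hat == pytest.approx([6.0, 6.0], abs=1e-6)
        shared = state.responsibilities.toarray()[-1]
        assert shared == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_read_conservation_and_normalization_every_iteration(self):
        rng = np.random.default_rng(0)
        m = dense_to_sparse_loglik(random_instance(rng, max_reads=8, max_alleles=3))
        state = run_vb(m, PriorConfig(alpha0=0.3, tol=1e-12, max_iter=300))
        rows = np.asarray(state.responsibilities.sum(axis=1)).ravel()
        assert rows == pytest.approx(np.ones(m.shape[0]), abs=1e-9)
        assert state.r_hat.sum() == pytest.approx(m.shape[0], abs=1e-6)
        assert state.alpha_hat == pytest.approx(0.3 + state.r_hat)
        assert state.theta_mean.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.theta_mean > 0).all()

    def test_elbo_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = dense_to_sparse_loglik(random_instance(rng))
            state = run_vb(m, PriorConfig(alpha0=0.2, tol=1e-10, max_iter=500))
            diffs = np.diff(state.elbo_trace)
            assert (diffs >= -1e-8).all()

    def test_matches_bruteforce_fixed_point(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            dense = random_instance(rng)
            alpha0 = float(rng.choice([0.1, 0.5, 1.0]))
            state = run_vb(dense_to_sparse_loglik(dense),
                           PriorConfig(alpha0=alpha0, tol=1e-12, max_iter=20000))
            oracle = fixed_point_read_counts(dense, alpha0, n_iter=5000)
            assert state.r_hat == pytest.approx(oracle, abs=1e-6)

    def test_nonconvergence_warns_not_raises(self):
        m = csr([[-1.0, -1.0001]] * 5)
        with pytest.warns(Warning, match="did not converge"):
            state = run_vb(m, PriorConfig(alpha0=1.0, tol=1e-15, max_iter=3))
        assert not state.converged

    def test_label_symmetry_full_permutation(self):
        rng = np.random.default_rng(21)
        dense = random_instance(rng, max_reads=8, max_alleles=3)
        T = dense.shape[1]
        perm = rng.permutation(T)
        state = run_vb(dense_to_sparse_loglik(dense),
                       PriorConfig(alpha0=0.5, tol=1e-12, max_iter=5000))
        state_p = run_vb(dense_to_sparse_loglik(dense[:, perm]),
                         PriorConfig(alpha0=0.5, tol=1e-12, max_iter=5000))
        assert state_p.r_hat == pytest.approx(state.r_hat[perm], abs=1e-9)
        assert state_p.theta_mean == pytest.approx(state.theta_mean[perm], abs=1e-9)


class TestSelectAlpha0:
    def test_singleton_grid_returned(self):
        m = csr([[-1.0, -2.0]])
        best, elbos = select_alpha0(m, PriorConfig(alpha0_grid=(0.7,)))
        assert best == 0.7 and set(elbos) == {0.7}

    def test_duplicate_grid_values_deduplicated(self):
        m = csr([[-1.0, -2.0], [-3.0, None]])
        best, elbos = select_alpha0(m, PriorConfig(alpha0_grid=(0.5, 0.5, 0.5)))
        assert best == 0.5 and list(elbos) == [0.5]

    def test_reported_elbo_matches_oracle_bound(self):
        rng = np.random.default_rng(31)
        dense = random_instance(rng, max_reads=6, max_alleles=2)
        cfg = PriorConfig(alpha0_grid=(0.1, 1.0), tol=1e-12, max_iter=20000)
        best, elbos = select_alpha0(dense_to_sparse_loglik(dense), cfg)
        for a0, bound in elbos.items():
            assert bound == pytest.approx(fixed_point_elbo(dense, a0, n_iter=5000),
                                          abs=1e-6)
        assert best == max(elbos, key=elbos.get)

    def test_argmax_of_final_elbo(self):
        # strongly unbalanced instance: small alpha0 (sparser prior) wins
        rows = [[-0.1, -9.0]] * 20
        best, elbos = select_alpha0(csr(rows), PriorConfig(alpha0_grid=(0.01, 1.0)))
        assert best == min(elbos, key=lambda a: -elbos[a])


class TestEstimatorInterface:
    def test_fitted_attributes_and_get_params(self):
        est = DirichletMultinomialVB(alpha0=1.0, tol=1e-6)
        m = csr([[-1.0, -1.0], [-1.0, None]])
        est.fit(m)
        assert est.get_params()["alpha0"] == 1.0
        assert est.converged_ and est.theta_.sum() == pytest.approx(1.0)
        assert est.r_.sum() == pytest.approx(2.0, abs=1e-6)

    def test_fit_predict_map_assignment(self):
        m = csr([[-0.5, -5.0], [-6.0, -0.5]])
        labels = DirichletMultinomialVB(alpha0=1.0).fit_predict(m)
        assert labels.tolist() == [0, 1]

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(DirichletMultinomialVB(alpha0=0.3, tol=1e-4))
        assert est.alpha0 == 0.3

    def test_rejects_empty_rows_and_positive_loglik(self):
        empty_row = sparse.csr_matrix((np.array([-1.0]), (np.array([0]), np.array([0]))),
                                      shape=(2, 2))
        with pytest.raises(ValueError):
            DirichletMultinomialVB(alpha0=1.0).fit(empty_row)
        bad = sparse.csr_matrix(np.array([[0.5]]))
        with pytest.raises(ValueError):
            DirichletMultinomialVB(alpha0=1.0).fit(bad)


def test_recovery_of_ninety_ten_mixture():
    """Reads 90/10 from two distinguishable alleles: posterior mean theta
    lands within 3 posterior SDs of (0.9, 0.1) at N=1000."""
    rng = np.random.default_rng(99)
    rows = []
    for _ in range(1000):
        src = 0 if rng.random() < 0.9 else 1
        row = [None, None]
        row[src] = -1.0  # distinguishable: reads hit only their source
        rows.append(row)
    state = run_vb(csr(rows), PriorConfig(alpha0=1.0))
    sd = state.theta_sd()
    target = np.array([0.9, 0.1])
    assert np.all(np.abs(state.theta_mean - target) <= 3 * sd + 3 * np.sqrt(0.09 / 1000))
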