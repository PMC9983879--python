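import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from magreml.grm import GRM, compute_grm
from magreml.simulate import SEMParams, scenario_params, simulate_dataset
from magreml.vcmodel import (
    BivariateREMLProblem,
    REMLError,
    VarCompEstimate,
    dense_reml_loglik,
    genetic_correlation,
    heritability,
    reml_fit,
    reml_fit_univariate,
    reml_loglik,
)

from conftest import make_random_instance, problem_from_arrays


class TestLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_canonical_equals_dense_oracle(self, seed):
        A, SG, SE, ym, yy, X = make_random_instance(seed, n=12, p_covars=2)
        prob = problem_from_arrays(A, ym, yy, X)
        ll_fast = reml_loglik(SG, SE, prob)
        ll_dense = dense_reml_loglik(A, SG, SE, ym, yy, X)
        assert ll_fast == pytest.approx(ll_dense, abs=1e-8)

    def test_iid_limit_closed_form(self):
        # Sigma_G = 0 with intercept-only design: the restricted likelihood
        # of an iid bivariate Gaussian, available in closed form.
        rng = np.random.default_rng(8)
        n = 40
        A = np.eye(n) * 0.0 + np.diag(rng.uniform(0.5, 2.0, n))  # any A: G is off
        ym, yy = rng.normal(size=n), rng.normal(size=n)
        X = np.ones((n, 1))
        SG = np.zeros((2, 2))
        SE = np.array([[1.3, 0.4], [0.4, 2.1]])
        prob = problem_from_arrays(A, ym, yy, X)
        ll = reml_loglik(SG, SE, prob)
        Yc = np.column_stack([ym - ym.mean(), yy - yy.mean()])
        S = Yc.T @ Yc
        Sinv = np.linalg.inv(SE)
        expected = -0.5 * (
            (2 * n - 2) * np.log(2 * np.pi)
            + n * np.log(np.linalg.det(SE))
            + (2 * np.log(n) - np.log(np.linalg.det(SE)))
            + np.trace(Sinv @ S)
        )
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_permutation_invariance(self):
        A, SG, SE, ym, yy, X = make_random_instance(1, n=10)
        perm = np.random.default_rng(2).permutation(10)
        ll1 = reml_loglik(SG, SE, problem_from_arrays(A, ym, yy, X))
        ll2 = reml_loglik(
            SG, SE,
            problem_from_arrays(A[np.ix_(perm, perm)], ym[perm], yy[perm], X[perm]),
        )
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_analytic_gradient_matches_finite_differences(self):
        A, SG, SE, ym, yy, X = make_random_instance(4, n=15, p_covars=2)
        prob = problem_from_arrays(A, ym, yy, X)
        g = prob.grad_vc(SG, SE)

        def ll_at(v):
            G = np.array([[v[0], v[1]], [v[1], v[2]]])
            E = np.array([[v[3], v[4]], [v[4], v[5]]])
            return prob.loglik(G, E)

        v0 = np.array([SG[0, 0], SG[0, 1], SG[1, 1], SE[0, 0], SE[0, 1], SE[1, 1]])
        h = 1e-6
        fd = np.array([
            (ll_at(v0 + h * e) - ll_at(v0 - h * e)) / (2 * h)
            for e in np.eye(6)
        ])
        np.testing.assert_allclose(g, fd, atol=1e-5, rtol=1e-5)

    def test_singular_block_raises_with_index(self):
        A, _, _, ym, yy, X = make_random_instance(0, n=8)
        prob = problem_from_arrays(A, ym, yy, X)
        with pytest.raises(REMLError, match="eigenvalue index"):
            prob.loglik(np.zeros((2, 2)), np.zeros((2, 2)))


class TestFit:
    def test_recovers_baseline_vcs_within_3_se(self, baseline_small,
                                               baseline_small_fit):
        true_G, true_E = baseline_small["params"].implied_sigma()
        truth = np.array([true_G[0, 0], true_G[0, 1], true_G[1, 1],
                          true_E[0, 0], true_E[0, 1], true_E[1, 1]])
        fit = baseline_small_fit
        assert fit.converged
        ses = np.sqrt(np.diag(fit.vcov_vc))
        assert (np.abs(fit.vc - truth) < 3 * ses).all()

    def test_constraint_pa_zeroes_mediator_genetics(self, baseline_small,
                                                    baseline_small_fit):
        prob = baseline_small["problem"]
        fit_pa = prob.fit(constraint="Pa", seed=1, compute_vcov=False,
                          warm_start=(baseline_small_fit.sigma_G,
                                      baseline_small_fit.sigma_E))
        assert fit_pa.sigma_G[0, 0] == 0.0
        assert fit_pa.sigma_G[0, 1] == 0.0
        assert fit_pa.loglik <= baseline_small_fit.loglik + 1e-6

    def test_constraint_pb_zeroes_environmental_covariance(
            self, baseline_small, baseline_small_fit):
        prob = baseline_small["problem"]
        fit_pb = prob.fit(constraint="Pb", seed=1, compute_vcov=False,
                          warm_start=(baseline_small_fit.sigma_G,
                                      baseline_small_fit.sigma_E))
        assert fit_pb.sigma_E[0, 1] == 0.0
        assert fit_pb.loglik <= baseline_small_fit.loglik + 1e-6

    def test_scale_equivariance(self):
        params = scenario_params("Baseline")
        geno, phenos = simulate_dataset(params, n=300, m_snps=400, seed=10)
        grm = compute_grm(geno)
        s = 3.0
        f1 = reml_fit(grm, phenos, traits=("M", "Y"), compute_vcov=False, seed=0)
        ph2 = phenos.copy()
        ph2["Y"] = s * ph2["Y"]
        f2 = reml_fit(grm, ph2, traits=("M", "Y"), compute_vcov=False, seed=0)
        D = np.diag([1.0, s])
        np.testing.assert_allclose(f2.sigma_G, D @ f1.sigma_G @ D, rtol=5e-3,
                                   atol=5e-3)
        np.testing.assert_allclose(f2.sigma_E, D @ f1.sigma_E @ D, rtol=5e-3,
                                   atol=5e-3)

    def test_univariate_heritability_recovery(self):
        # generative sigma_G = 0.25, sigma_E = 0.75 -> h2 = 0.25
        params = SEMParams(a=np.sqrt(0.125), g=np.sqrt(0.125),
                           f=np.sqrt(0.75), b=0.0, c=0.0, e=1.0)
        geno, phenos = simulate_dataset(params, n=500, m_snps=600, seed=21)
        grm = compute_grm(geno)
        sg, se, _ = reml_fit_univariate(grm, phenos["M"].to_numpy(), seed=0)
        h2 = sg / (sg + se)
        assert h2 == pytest.approx(0.25, abs=0.2)
        # Eq-style arithmetic on the true VCs is exact
        assert 0.25 / (0.25 + 0.75) == 0.25

    def test_missing_trait_small_n_uses_exact_dense_path(self):
        params = scenario_params("Baseline")
        geno, phenos = simulate_dataset(params, n=60, m_snps=200, seed=3)
        grm = compute_grm(geno)
        ph = phenos.copy()
        ph.iloc[:5, ph.columns.get_loc("Y")] = np.nan
        fit = reml_fit(grm, ph, traits=("M", "Y"), compute_vcov=False,
                       min_n=10, dense_max=200)
        assert fit.n_used == {"M": 60, "Y": 55}
        # the exact fit uses the extra mediator-only rows: its likelihood is
        # evaluated on more data, so just check sanity of the estimates
        assert np.linalg.eigvalsh(fit.sigma_G).min() > -1e-8

    def test_missing_trait_large_falls_back_to_complete_case(self):
        params = scenario_params("Baseline")
        geno, phenos = simulate_dataset(params, n=80, m_snps=200, seed=4)
        grm = compute_grm(geno)
        ph = phenos.copy()
        ph.iloc[:6, ph.columns.get_loc("Y")] = np.nan
        with pytest.warns(RuntimeWarning, match="complete-case"):
            fit = reml_fit(grm, ph, traits=("M", "Y"), compute_vcov=False,
                           min_n=10, dense_max=10)
        assert fit.n_used == {"M": 74, "Y": 74}

    def test_same_trait_twice_rejected(self, baseline_small):
        with pytest.raises(ValueError, match="different traits"):
            reml_fit(baseline_small["grm"], baseline_small["phenos"],
                     traits=("M", "M"))

    def test_too_small_sample_rejected(self):
        params = scenario_params("Baseline")
        geno, phenos = simulate_dataset(params, n=10, m_snps=50, seed=5)
        with pytest.raises(ValueError, match="minimum"):
            reml_fit(compute_grm(geno), phenos, traits=("M", "Y"))


class TestDerivedQuantities:
    def _vc(self, vec, vcov=None):
        G = np.array([[vec[0], vec[1]], [vec[1], vec[2]]])
        E = np.array([[vec[3], vec[4]], [vec[4], vec[5]]])
        return VarCompEstimate(sigma_G=G, sigma_E=E, loglik=0.0,
                               vcov_vc=vcov, n_used={"M": 0, "Y": 0},
                               converged=True)

    def test_heritability_values(self):
        vc = self._vc([0.25, 0.0, 0.0, 0.75, 0.0, 1.0])
        assert heritability(vc, "M")[0] == pytest.approx(0.25)
        assert heritability(vc, "Y")[0] == 0.0

    def test_heritability_zero_total_variance_errors(self):
        vc = self._vc([0.25, 0.0, 0.0, 0.75, 0.0, 1.0])
        vc.sigma_G[1, 1] = vc.sigma_E[1, 1] = 0.0
        with pytest.raises(ValueError, match="zero total variance"):
            heritability(vc, "Y")

    def test_heritability_se_matches_numerical_jacobian(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(6, 6))
        vcov = B @ B.T / 6
        vec = np.array([0.4, 0.2, 0.6, 0.6, 0.1, 0.9])
        vc = self._vc(vec, vcov)
        _, se = heritability(vc, "Y")

        def h2_of(v):
            return v[2] / (v[2] + v[5])

        h = 1e-7
        J = np.array([(h2_of(vec + h * e) - h2_of(vec - h * e)) / (2 * h)
                      for e in np.eye(6)])
        se_num = np.sqrt(J @ vcov @ J)
        assert se == pytest.approx(se_num, rel=1e-6)

    def test_genetic_correlation_limits(self):
        vc = self._vc([2.0, np.sqrt(10.0), 5.0, 1.0, 0.0, 1.0])
        assert genetic_correlation(vc)[0] == pytest.approx(1.0)
        vc0 = self._vc([2.0, 0.0, 5.0, 1.0, 0.0, 1.0])
        assert genetic_correlation(vc0)[0] == 0.0

    def test_genetic_correlation_baseline_value(self):
        vc = self._vc([2.0, 3.0, 5.0, 1.0, 1.0, 2.0])
        assert genetic_correlation(vc)[0] == pytest.approx(3 / np.sqrt(10))

    def test_genetic_correlation_undefined_at_zero_variance(self):
        vc = self._vc([0.0, 0.0, 5.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="not identified"):
            genetic_correlation(vc)


class TestVcov:
    def test_vcov_is_symmetric_psd(self, baseline_small_fit):
        V = baseline_small_fit.vcov_vc
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_reported_se_scale_plausible(self, baseline_small_fit):
        # SEs at n=500 for VCs of magnitude ~1-5 should be O(0.1-1)
        ses = np.sqrt(np.diag(baseline_small_fit.vcov_vc))
        assert (ses > 1e-3).all() and (ses < 5).all()
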