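
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from ahatraj import trajectories as tr


def _make_growth_data(rng, n=400, T=5, lam=None, resid=3.0,
                      mu=(70.0, -10.0), cov=((25.0, 0.0), (0.0, 9.0))):
    lam = np.linspace(0, 1, T) if lam is None else np.asarray(lam)
    eta = rng.multivariate_normal(mu, cov, size=n)
    return eta[:, [0]] + lam[None, :] * eta[:, [1]] + rng.normal(0, resid, (n, T)), eta


class TestLgcm:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        lam = np.array([0.0, 0.35, 0.7, 1.0])
        Y, eta = _make_growth_data(rng, n=300, T=4, lam=lam, resid=0.0)
        fit = tr.fit_lgcm(Y, shape="latent_basis", seed=1)
        np.testing.assert_allclose(fit.mu[0], [70.0, -10.0], atol=0.5)
        np.testing.assert_allclose(fit.basis, lam, atol=0.01)
        assert np.all(fit.sigma2 < 0.05)

    def test_latent_basis_recovers_linear_loadings_on_linear_truth(self):
        rng = np.random.default_rng(1)
        Y, _ = _make_growth_data(rng, n=800, T=5)
        fit = tr.fit_lgcm(Y, shape="latent_basis", seed=0)
        np.testing.assert_allclose(fit.basis, np.linspace(0, 1, 5), atol=0.05)

    def test_single_wave_unidentified(self):
        Y = np.full((50, 4), np.nan)
        Y[:, 0] = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError, match="unidentified"):
            tr.fit_lgcm(Y)

    def test_shape_selection_on_linear_truth(self):
        rng = np.random.default_rng(5)
        Y, _ = _make_growth_data(rng, n=600, T=5)
        best, report = tr.select_growth_shape(Y, seed=0)
        assert best == "linear"
        assert set(report) == {"linear", "quadratic", "latent_basis"}


class TestGmm:
    def test_k1_equals_lgcm(self):
        rng = np.random.default_rng(2)
        Y, _ = _make_growth_data(rng, n=300, T=4)
        lg = tr.fit_lgcm(Y, shape="latent_basis", seed=3)
        gm = tr.fit_gmm(Y, tr.GrowthSpec(shape="latent_basis", K=1, seed=3))
        assert gm.loglik == pytest.approx(lg.loglik, abs=1e-3)

    def test_three_class_recovery(self, growth_scores):
        scores, cohort = growth_scores
        spec = tr.GrowthSpec(K=3, seed=7, n_starts=20, n_final=5)
        fit = tr.fit_gmm(scores, spec)
        ari = adjusted_rand_score(cohort.true_class, fit.assignments)
        assert ari > 0.8
        assert fit.fit["entropy"] > 0.8
        # class mean intercepts match the generating configuration (sorted)
        truth = sorted(m[0] for m in cohort.config.class_growth_means)
        est = sorted(fit.mu[:, 0])
        np.testing.assert_allclose(est, truth, atol=3.0)

    def test_em_loglik_monotone(self, growth_scores):
        scores, _ = growth_scores
        fit = tr.fit_gmm(scores[:800], tr.GrowthSpec(K=2, seed=1, n_starts=6,
                                                     n_final=2))
        h = fit.loglik_history
        assert np.all(np.diff(h) >= -1e-6 * (np.abs(h[:-1]) + 1))

    def test_posterior_rows_sum_to_one_and_modal_argmax(self, growth_scores):
        scores, _ = growth_scores
        fit = tr.fit_gmm(scores[:600], tr.GrowthSpec(K=2, seed=2, n_starts=6,
                                                     n_final=2))
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(fit.assignments, fit.posterior.argmax(axis=1))

    def test_replication_from_stored_seed(self, growth_scores):
        scores, _ = growth_scores
        spec = tr.GrowthSpec(K=2, seed=5, n_starts=8, n_final=3)
        fit = tr.fit_gmm(scores[:700], spec)
        re = tr.refit_with_seed(scores[:700], spec, fit.start_seeds[0])
        assert re.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_lcga_fixes_growth_variances(self, growth_scores):
        scores, _ = growth_scores
        fit = tr.fit_gmm(scores[:600], tr.GrowthSpec(K=2, seed=3, lcga=True,
                                                     n_starts=6, n_final=2))
        assert np.all(fit.psi == 0)

    def test_coverage_abort(self):
        rng = np.random.default_rng(0)
        Y, _ = _make_growth_data(rng, n=200, T=4)
        Y[:195, 2] = np.nan  # kill coverage of wave 2 pairs
        with pytest.raises(ValueError, match="coverage"):
            tr.fit_gmm(Y, tr.GrowthSpec(K=2, seed=0))


class TestEntropy:
    def test_one_hot_is_one(self):
        p = np.eye(3)[np.array([0, 1, 2, 1])]
        assert tr.entropy(p) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert tr.entropy(np.full((5, 4), 0.25)) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        p = np.array([[0.9, 0.1], [0.8, 0.2], [0.5, 0.5]])
        assert tr.entropy(p) == pytest.approx(0.2698, abs=1e-3)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            tr.entropy(np.ones((5, 1)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=20)
        e = tr.entropy(p)
        assert -1e-9 <= e <= 1 + 1e-9
        perm = rng.permutation(3)
        assert tr.entropy(p[:, perm]) == pytest.approx(e, abs=1e-12)


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic, ssabic = tr.information_criteria(-100.0, 5, 100)
        assert aic == 210.0
        assert ssabic == pytest.approx(200 + 5 * np.log(102 / 24), abs=1e-9)

    def test_zero_params_all_equal(self):
        aic, bic, ssabic = tr.information_criteria(-50.0, 0, 30)
        assert aic == bic == ssabic == 100.0


class TestLmrTests:
    def _fit_pair(self, seed=0, n=300, separated=False):
        rng = np.random.default_rng(seed)
        if separated:
            cls = rng.choice(2, size=n, p=[0.5, 0.5])
            mu = np.array([[50.0, -5.0], [85.0, -30.0]])[cls]
            eta = mu + rng.multivariate_normal([0, 0], [[16, 0], [0, 9]], size=n)
            lam = np.linspace(0, 1, 4)
            Y = eta[:, [0]] + lam[None, :] * eta[:, [1]] + rng.normal(0, 4, (n, 4))
        else:
            Y, _ = _make_growth_data(rng, n=n, T=4)
        f1 = tr.fit_gmm(Y, tr.GrowthSpec(K=1, seed=seed, n_starts=4, n_final=2))
        f2 = tr.fit_gmm(Y, tr.GrowthSpec(K=2, seed=seed, n_starts=8, n_final=3))
        return f1, f2

    def test_power_on_separated_classes(self):
        f1, f2 = self._fit_pair(seed=3, n=500, separated=True)
        p_v, p_a = tr.lmr_tests(f2, f1)
        assert p_v < 0.001 and p_a < 0.001

    def test_adjusted_p_not_smaller(self):
        f1, f2 = self._fit_pair(seed=4)
        p_v, p_a = tr.lmr_tests(f2, f1)
        assert p_a >= p_v

    def test_bootstrap_method_returns_probability(self):
        f1, f2 = self._fit_pair(seed=5, n=150)
        p_v, p_a = tr.lmr_tests(f2, f1, method="bootstrap", n_boot=9, seed=1)
        assert 0.0 < p_v <= 1.0 and p_v == p_a

    def test_k_must_differ_by_one(self):
        f1, f2 = self._fit_pair(seed=6, n=150)
        with pytest.raises(ValueError):
            tr.lmr_tests(f1, f2)


class TestCoverage:
    def test_complete_panel_all_ones(self):
        Y = np.zeros((20, 3))
        cov, ok = tr.coverage_check(Y)
        np.testing.assert_allclose(cov, 1.0)
        assert ok

    def test_partial_coverage_value(self):
        Y = np.zeros((100, 2))
        Y[22:, 1] = np.nan  # 22% observe both waves
        cov, ok = tr.coverage_check(Y)
        assert cov[0, 1] == pytest.approx(0.22)
        assert ok

    def test_empty_wave_fails(self):
        Y = np.zeros((50, 2))
        Y[:, 1] = np.nan
        cov, ok = tr.coverage_check(Y)
        assert cov.min() == 0.0
        assert not ok


class TestSelectK:
    def _stub(self, K, loglik, n_params, n, counts, avg_post, fit):
        q = 2
        return tr.GmmFit(
            spec=tr.GrowthSpec(K=K, seed=0), pi=np.asarray(counts) / n,
            mu=np.zeros((K, q)), psi=np.eye(q), sigma2=np.ones(4),
            loadings=np.column_stack([np.ones(4), np.linspace(0, 1, 4)]),
            loglik=loglik, n_params=n_params, n=n,
            posterior=np.full((1, K), 1.0 / K), assignments=np.zeros(1, dtype=int),
            fit=fit, coverage=np.ones((4, 4)), loglik_history=np.array([loglik]),
            avg_posterior=np.asarray(avg_post), class_counts=np.asarray(counts),
            start_seeds=[0], converged=True)

    def test_tiny_class_disqualifies_larger_k(self):
        n = 2000
        fits = {
            2: self._stub(2, -10_000.0, 10, n, [700, 1300], [0.9, 0.9],
                          {"aic": 20020.0, "bic": 20076.0, "ssabic": 20044.0,
                           "entropy": 0.9}),
            3: self._stub(3, -9_800.0, 13, n, [650, 1150, 200], [0.9, 0.92, 0.88],
                          {"aic": 19626.0, "bic": 19699.0, "ssabic": 19657.0,
                           "entropy": 0.88}),
            4: self._stub(4, -9_750.0, 16, n, [640, 1130, 190, 40],
                          [0.9, 0.92, 0.88, 0.8],
                          {"aic": 19532.0, "bic": 19622.0, "ssabic": 19570.0,
                           "entropy": 0.86}),
        }
        chosen, log = tr.select_K(fits)
        assert chosen == 3  # K=4 rejected: a class at 2% of the sample

    def test_all_criteria_favour_two(self):
        n = 1000
        fits = {
            2: self._stub(2, -5_000.0, 10, n, [400, 600], [0.9, 0.9],
                          {"aic": 10020.0, "bic": 10069.0, "ssabic": 10037.0,
                           "entropy": 0.9}),
            3: self._stub(3, -4_999.5, 13, n, [390, 590, 20], [0.9, 0.9, 0.6],
                          {"aic": 10025.0, "bic": 10089.0, "ssabic": 10048.0,
                           "entropy": 0.8}),
        }
        chosen, log = tr.select_K(fits)
        assert chosen == 2

    def test_no_admissible_k_warns(self):
        n = 1000
        fits = {
            2: self._stub(2, -5_000.0, 10, n, [15, 985], [0.6, 0.9],
                          {"aic": 10020.0, "bic": 10069.0, "ssabic": 10037.0,
                           "entropy": 0.5}),
        }
        with pytest.warns(UserWarning, match="compromise"):
            chosen, _ = tr.select_K(fits)
        assert chosen == 2


def test_label_permutation_leaves_statistics_unchanged(growth_scores):
    scores, _ = growth_scores
    fit = tr.fit_gmm(scores[:500], tr.GrowthSpec(K=3, seed=9, n_starts=8,
                                                 n_final=3))
    perm = np.array([2, 0, 1])
    assert tr.entropy(fit.posterior[:, perm]) == pytest.approx(
        fit.fit["entropy"], abs=1e-12)
    aic, bic, ssabic = tr.information_criteria(fit.loglik, fit.n_params, fit.n)
    assert aic == pytest.approx(fit.fit["aic"])
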