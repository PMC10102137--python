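import numpy as np
import pytest
from scipy import stats

from ahatraj import dimensionality as dm
from ahatraj.synthetic import simulate_ordinal_factor_data


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestBvnCdf:
    def test_against_scipy(self, rng):
        for rho in (-0.8, -0.3, 0.0, 0.5, 0.9):
            mvn = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            pts = [(-1.2, 0.4), (0.0, 0.0), (0.0, 1.1), (2.0, -2.0), (0.7, 0.7)]
            for h, k in pts:
                assert dm.bvn_cdf(h, k, rho) == pytest.approx(mvn.cdf([h, k]), abs=1e-10)

    def test_limits(self):
        assert dm.bvn_cdf(-np.inf, 0.5, 0.3) == 0.0
        assert dm.bvn_cdf(np.inf, 0.5, 0.3) == pytest.approx(stats.norm.cdf(0.5))
        assert dm.bvn_cdf(np.inf, np.inf, -0.5) == 1.0


class TestPolychoric:
    def test_null_case(self, rng):
        x = rng.integers(0, 3, 8000).astype(float)
        y = rng.integers(0, 2, 8000).astype(float)
        assert abs(dm.polychoric_pair(x, y)) < 0.05

    def test_recovers_generating_correlation(self, rng):
        rho = 0.5
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=20000)
        x = (z[:, 0] > -0.5).astype(float) + (z[:, 0] > 0.7)
        y = (z[:, 1] > 0.2).astype(float)
        assert dm.polychoric_pair(x, y) == pytest.approx(rho, abs=0.03)

    def test_concordant_pair_capped(self, rng):
        x = rng.integers(0, 2, 400).astype(float)
        assert dm.polychoric_pair(x, x.copy()) >= 0.99

    def test_single_category_item_excluded(self, rng):
        X = np.column_stack([
            rng.integers(0, 2, 200), rng.integers(0, 2, 200),
            np.zeros(200),
        ]).astype(float)
        R, keep, dropped = dm.polychoric_matrix(X)
        assert list(dropped) == [2]
        assert R.shape == (2, 2)

    def test_matrix_is_psd_and_symmetric(self, rng):
        L = np.array([[0.7], [0.6], [0.8], [0.5]])
        X = simulate_ordinal_factor_data(L, 1500, rng)
        R, keep, _ = dm.polychoric_matrix(X)
        assert np.allclose(R, R.T)
        assert np.linalg.eigvalsh(R).min() > -1e-8


class TestEfa:
    def test_two_block_structure(self, rng):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.85
        L[4:, 1] = 0.85
        X = simulate_ordinal_factor_data(L, 5000, rng)
        R, _, _ = dm.polychoric_matrix(X)
        sol = dm.efa(R, 2, seed=1)
        Ls = np.abs(sol.loadings)
        prim = Ls.max(axis=1)
        cross = Ls.min(axis=1)
        assert np.all(prim > 0.6)
        assert np.all(cross < 0.15)

    def test_identity_matrix_zero_communalities(self):
        sol = dm.efa(np.eye(6), 2, seed=0)
        assert np.all(sol.communalities <= 0.06)

    def test_four_block_scree(self, rng):
        L = np.zeros((12, 4))
        for f in range(4):
            L[3 * f:3 * f + 3, f] = 0.8
        X = simulate_ordinal_factor_data(L, 4000, rng)
        R, _, _ = dm.polychoric_matrix(X)
        sol = dm.efa(R, 4, seed=0)
        eigs = sol.eigenvalues
        assert eigs[3] > 2 * eigs[4]  # four dominant roots

    def test_rotation_preserves_reproduced_matrix(self, rng):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.8
        L[4:, 1] = 0.8
        L[3, 1] = 0.3
        X = simulate_ordinal_factor_data(L, 3000, rng)
        R, _, _ = dm.polychoric_matrix(X)
        sol = dm.efa(R, 2, seed=0)
        # Lambda Phi Lambda' has the communalities on the diagonal and must
        # reproduce the unrotated common part
        rep = sol.loadings @ sol.factor_correlations @ sol.loadings.T
        resid = R - rep
        np.fill_diagonal(resid, 0.0)
        assert np.abs(resid).max() < 0.1

    def test_too_many_factors_rejected(self):
        with pytest.raises(ValueError):
            dm.efa(np.eye(3), 3)

    def test_select_n_factors_finds_four(self, rng):
        L = np.zeros((12, 4))
        for f in range(4):
            L[3 * f:3 * f + 3, f] = 0.8
        g = np.full(4, 0.6)
        Phi = np.outer(g, g)
        np.fill_diagonal(Phi, 1.0)
        X = simulate_ordinal_factor_data(L, 4000, rng, factor_corr=Phi)
        R, _, _ = dm.polychoric_matrix(X)
        m, report = dm.select_n_factors(R, 4000, max_factors=6, seed=0)
        assert m == 4


class TestRetainItems:
    def _sol(self, loadings):
        L = np.asarray(loadings, dtype=float)
        return dm.FactorSolution(
            loadings=L, factor_correlations=np.eye(L.shape[1]),
            eigenvalues=np.ones(L.shape[0]), communalities=(L ** 2).sum(1),
            uniquenesses=1 - (L ** 2).sum(1), n_factors=L.shape[1],
            criterion=0.0, converged=True)

    def test_rules(self):
        sol = self._sol([
            [0.33, 0.35, 0.05, 0.02],   # cross-loader: dropped
            [0.20, 0.10, 0.05, 0.02],   # loads nowhere: dropped
            [0.40, 0.10, 0.05, 0.02],   # clean: retained
            [-0.45, 0.05, 0.02, 0.01],  # sign-invariant: retained
        ])
        retained, log = dm.retain_items(sol)
        assert list(retained) == [2, 3]
        reasons = dict(log)
        assert reasons[0] == "cross-loading" and reasons[1] == "no-factor"

    def test_idempotent_and_order_independent(self):
        L = np.array([[0.4, 0.1], [0.35, 0.34], [0.1, 0.5], [0.2, 0.1]])
        sol = self._sol(L)
        r1, _ = dm.retain_items(sol)
        sub = self._sol(L[r1])
        r2, _ = dm.retain_items(sub)
        assert len(r2) == len(r1)  # retained set survives re-application
        perm = np.array([3, 1, 0, 2])
        rp, _ = dm.retain_items(self._sol(L[perm]))
        assert sorted(perm[rp]) == sorted(r1)


class TestCfa:
    def test_true_second_order_model_fits_well(self, rng):
        g = np.array([0.7, 0.75, 0.8, 0.65])
        Phi = np.outer(g, g)
        np.fill_diagonal(Phi, 1.0)
        L = np.zeros((12, 4))
        for f in range(4):
            L[3 * f:3 * f + 3, f] = 0.75
        X = simulate_ordinal_factor_data(L, 5000, rng, factor_corr=Phi)
        fi, lam, gam, heywood = dm.cfa_second_order(X, np.repeat(np.arange(4), 3))
        assert fi.cfi > 0.95
        assert fi.rmsea < 0.06
        assert fi.rmsea_ci[0] <= fi.rmsea <= fi.rmsea_ci[1]
        assert np.all(gam > 0)  # general factor loads positively everywhere
        assert not heywood

    def test_saturated_single_factor_toy(self, rng):
        L = np.full((3, 1), 0.7)
        X = simulate_ordinal_factor_data(L, 2000, rng)
        fi, lam, gam, _ = dm.cfa_second_order(X, np.zeros(3, dtype=int))
        assert fi.df == 0
        assert fi.chi_square == pytest.approx(0.0, abs=1e-4)

    def test_independent_items_reject_fit(self, rng):
        X = rng.integers(0, 3, size=(3000, 8)).astype(float)
        fi, _, _, _ = dm.cfa_second_order(X, np.repeat(np.arange(4), 2))
        assert fi.cfi < 0.5 or fi.chi_square < fi.df + 10  # null data: no common factor


class TestFitIndices:
    def test_perfect_fit(self):
        fi = dm.fit_indices(100.0, 100, 500.0, 120, 1000)
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_rmsea_formula(self):
        fi = dm.fit_indices(200.0, 100, 2000.0, 120, 1001)
        assert fi.rmsea == pytest.approx(np.sqrt(100 / 100_000), abs=1e-6)

    def test_cfi_floor(self):
        fi = dm.fit_indices(500.0, 100, 300.0, 120, 1000)
        assert fi.cfi == 0.0

    def test_df_ordering_enforced(self):
        with pytest.raises(ValueError):
            dm.fit_indices(100.0, 120, 90.0, 100, 500)
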