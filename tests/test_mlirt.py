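import types
import warnings

import numpy as np
import pytest

from ahatraj import item_prep as ip
from ahatraj import mlirt as ml
from ahatraj import synthetic as syn


@pytest.fixture(scope="module")
def small_fit_and_truth():
    """A quick variant-a fit on a 250-person, 10-item, 3-wave GRM cohort."""
    cfg = syn.SimConfig(n_persons=250, n_waves=3, seed=17, item_bank_sizes=(10, 0),
                        basis_loadings=(0.0, 0.5, 1.0), missing_rate=0.02,
                        attrition_hazard=0.05)
    cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
    panel = ip.prepare_panel(cohort)
    spec = ml.MlirtSpec(variant="a", n_iter=800, n_burnin=200, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ml.fit_mlirt(panel.responses, panel.n_categories, spec,
                           include=panel.personwave_eligible)
    return fit, cohort, panel


class TestFitMlirt:
    def test_trait_recovery(self, small_fit_and_truth):
        fit, cohort, _ = small_fit_and_truth
        m = fit.included
        corr = np.corrcoef(fit.theta_eap[m], cohort.theta_std[m])[0, 1]
        assert corr > 0.85

    def test_discriminations_positive_thresholds_ordered(self, small_fit_and_truth):
        fit, _, _ = small_fit_and_truth
        assert np.all(fit.a_mean > 0)
        for thr in fit.thresholds_mean:
            assert np.all(np.diff(thr) > 0) or len(thr) < 2

    def test_empty_personwave_excluded(self, small_fit_and_truth):
        fit, cohort, panel = small_fit_and_truth
        # person-waves failing the half-battery gate carry no score
        assert np.isnan(fit.theta_eap[~fit.included]).all()

    def test_disconnected_design_rejected(self):
        resp = np.full((30, 2, 2), np.nan)
        rng = np.random.default_rng(0)
        resp[:, 0, 0] = rng.integers(0, 2, 30)  # item 0 only at wave 0
        resp[:, 1, 1] = rng.integers(0, 2, 30)  # item 1 only at wave 1
        with pytest.raises(ValueError, match="disconnected"):
            ml.fit_mlirt(resp, np.array([2, 2]), ml.MlirtSpec(n_iter=50, n_burnin=10))

    def test_seed_reproducibility(self):
        cfg = syn.SimConfig(n_persons=80, n_waves=2, seed=4, item_bank_sizes=(6, 0),
                            basis_loadings=(0.0, 1.0), missing_rate=0.0,
                            attrition_hazard=0.0)
        cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
        panel = ip.prepare_panel(cohort)
        spec = ml.MlirtSpec(variant="a", n_iter=300, n_burnin=100, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = ml.fit_mlirt(panel.responses, panel.n_categories, spec)
            f2 = ml.fit_mlirt(panel.responses, panel.n_categories, spec)
        np.testing.assert_allclose(f1.theta_eap[f1.included],
                                   f2.theta_eap[f2.included])
        assert f1.dic == f2.dic

    def test_chains_agree_across_seeds(self, small_fit_and_truth):
        fit, cohort, panel = small_fit_and_truth
        spec = ml.MlirtSpec(variant="a", n_iter=800, n_burnin=200, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            other = ml.fit_mlirt(panel.responses, panel.n_categories, spec,
                                 include=panel.personwave_eligible)
        a, b = fit.theta_eap[fit.included], other.theta_eap[other.included]
        assert np.corrcoef(a, b)[0, 1] > 0.99


class TestScoreStability:
    def test_uninformative_item_barely_moves_scores(self, small_fit_and_truth):
        fit, cohort, panel = small_fit_and_truth
        rng = np.random.default_rng(0)
        n, T, J = panel.responses.shape
        noise = rng.integers(0, 2, size=(n, T, 1)).astype(float)
        aug = np.concatenate([panel.responses, noise], axis=2)
        ncat = np.r_[panel.n_categories, 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit2 = ml.fit_mlirt(aug, ncat, ml.MlirtSpec(variant="a", n_iter=800,
                                                        n_burnin=200, seed=3),
                                include=panel.personwave_eligible)
        a = fit.theta_eap[fit.included]
        b = fit2.theta_eap[fit.included]
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_wave_variance_credible_intervals_cover_truth(self):
        """Shared wave-deviation variance: 95% credible intervals cover the
        generating value in most small replicates (scaled-down calibration)."""
        truth = 0.7 ** 2
        cover = 0
        for rep in range(8):
            cfg = syn.SimConfig(n_persons=150, n_waves=4, seed=300 + rep,
                                item_bank_sizes=(8, 0),
                                basis_loadings=(0.0, 0.4, 0.7, 1.0),
                                missing_rate=0.0, attrition_hazard=0.0,
                                item_wave_sd=(0.7, 0.0))
            cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
            pp = ip.prepare_panel(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ml.fit_mlirt(pp.responses, pp.n_categories,
                                   ml.MlirtSpec(variant="c", n_iter=600,
                                                n_burnin=200, seed=rep),
                                   include=pp.personwave_eligible)
            lo, hi = np.percentile(fit.sigma2_b_draws[:, 0], [2.5, 97.5])
            cover += lo <= truth <= hi
        assert cover >= 6


class TestGrmLoglik:
    def test_duplicated_data_doubles_deviance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 50)
        theta = rng.normal(size=50)
        ll = ml.grm_loglik(y, 1.2, (-0.5, 0.6), theta).sum()
        ll2 = ml.grm_loglik(np.r_[y, y], 1.2, (-0.5, 0.6), np.r_[theta, theta]).sum()
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_probabilities_normalised(self):
        theta = np.linspace(-3, 3, 31)
        total = sum(
            np.exp(ml.grm_loglik(np.full(31, c), 0.9, (-1.0, 0.4, 1.3), theta))
            for c in range(4))
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_dic_components_consistent(self, small_fit_and_truth):
        fit, _, _ = small_fit_and_truth
        assert fit.dic == pytest.approx(fit.dbar + fit.p_d)
        assert fit.p_d > 0          # posterior-mean plug-in fits better
        assert fit.dbar > fit.dhat


class TestReliabilityAndIcc:
    def test_reliability_limits(self):
        stub = types.SimpleNamespace(
            included=np.ones((4, 1), dtype=bool),
            theta_eap=np.array([[-1.0], [0.0], [1.0], [2.0]]),
            theta_sd=np.zeros((4, 1)))
        assert ml.eap_reliability(stub) == pytest.approx(1.0)
        noisy = types.SimpleNamespace(
            included=np.ones((4, 1), dtype=bool),
            theta_eap=np.zeros((4, 1)),
            theta_sd=np.ones((4, 1)))
        assert ml.eap_reliability(noisy) == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        stub = types.SimpleNamespace(
            included=np.ones((3, 1), dtype=bool),
            theta_eap=np.zeros((3, 1)), theta_sd=np.zeros((3, 1)))
        with pytest.raises(ValueError):
            ml.eap_reliability(stub)

    def test_icc_undefined_for_variant_a(self, small_fit_and_truth):
        fit, _, _ = small_fit_and_truth
        with pytest.raises(ValueError):
            ml.icc_wave(fit)

    def test_icc_interval_ordered_and_near_truth(self):
        # wave intercept deviations with variance 1 against probit residual 1
        cfg = syn.SimConfig(n_persons=300, n_waves=4, seed=23, item_bank_sizes=(12, 0),
                            basis_loadings=(0.0, 0.4, 0.7, 1.0), missing_rate=0.0,
                            attrition_hazard=0.0, item_wave_sd=(1.0, 0.0))
        cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
        panel = ip.prepare_panel(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ml.fit_mlirt(panel.responses, panel.n_categories,
                               ml.MlirtSpec(variant="c", n_iter=900, n_burnin=300,
                                            seed=2),
                               include=panel.personwave_eligible)
        med, (lo, hi) = ml.icc_wave(fit)
        assert lo <= med <= hi
        assert med == pytest.approx(0.5, abs=0.15)


class TestRescale:
    def test_endpoints_midpoint_monotone(self):
        x = np.array([2.0, 3.0, 4.0, 6.0])
        s = ml.rescale_0_100(x)
        assert s[0] == 0.0 and s[-1] == 100.0
        assert ml.rescale_0_100(np.array([0.0, 1.0, 2.0]))[1] == 50.0
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        sv = ml.rescale_0_100(v)
        assert np.all(np.argsort(sv) == np.argsort(v))

    def test_tscore_variant_monotone(self):
        v = np.array([-2.0, 0.0, 1.0, 3.0])
        s = ml.rescale_0_100(v, method="tscore")
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 100))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ml.rescale_0_100(np.array([1.0, 1.0, 1.0]))


class TestModelSelection:
    def _stub(self, rel, dic):
        return types.SimpleNamespace(eap_reliability=rel, dic=dic)

    def test_published_pattern_selects_variant_d(self):
        fits = {"a": self._stub(0.892, 1368772), "b": self._stub(0.912, 1323489),
                "c": self._stub(0.903, 1323538), "d": self._stub(0.925, 1198613)}
        chosen, log = ml.select_mlirt_model(fits)
        assert chosen == "d"

    def test_tie_logs_no_conflict(self):
        fits = {"a": self._stub(0.9, 100.0), "b": self._stub(0.9, 100.0)}
        chosen, log = ml.select_mlirt_model(fits)
        assert chosen in ("a", "b")

    def test_conflict_prefers_dic(self):
        fits = {"b": self._stub(0.95, 210.0), "c": self._stub(0.90, 200.0)}
        chosen, log = ml.select_mlirt_model(fits)
        assert chosen == "c"
        assert any("disagree" in line for line in log)
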