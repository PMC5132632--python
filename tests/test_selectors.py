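"""The six selection methods: oracles, calibration properties, API contract."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from exposobench import selectors as sel
from exposobench.errors import ValidationError
from exposobench.selectors import (
    DSASelector,
    ElasticNetSelector,
    ESSConfig,
    ESSSelector,
    EWASMLRSelector,
    EWASSelector,
    SPLSSelector,
    ridge_refit,
)
from exposobench.selectors._ess import _size_prior_logpmf
from exposobench.selectors._ewas import _univariate_stats

from conftest import make_orthogonal_design

ALL_SELECTORS = [EWASSelector, EWASMLRSelector, ElasticNetSelector,
                 SPLSSelector, ESSSelector, DSASelector]


def signal_data(rng, n, p, idx, r2=0.5):
    """Gaussian design with one or more unit-effect predictors at target R^2."""
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[list(idx)] = 1.0
    v = float(beta @ beta)
    sigma2 = v * (1 - r2) / r2
    y = X @ beta + rng.normal(0, np.sqrt(sigma2), n)
    return X, y


class TestEWAS:
    def test_pvalues_match_textbook_t_test(self, rng):
        X = rng.standard_normal((60, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.standard_normal(60)
        slope, pvals = _univariate_stats(X, y)
        for j in range(10):
            fit = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert pvals[j] == pytest.approx(fit.pvalues[1], abs=1e-10)
            assert slope[j] == pytest.approx(fit.params[1], abs=1e-10)

    def test_strong_signal_always_detected(self):
        # population R^2 = 0.5 at n = 1200: power is essentially 1
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y = signal_data(rng, 1200, 10, [4], r2=0.5)
            res = sel.ewas(X, y, correction="bh", level=0.05)
            assert 4 in res.selected

    def test_bonferroni_familywise_error_control(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((100, 50))
            y = rng.standard_normal(100)
            res = sel.ewas(X, y, correction="bonferroni", level=0.05)
            hits += bool(res.selected)
        assert hits / 200 <= 0.08

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((80, 8))
        y = X[:, 1] + rng.standard_normal(80)
        _, p1 = _univariate_stats(X, y)
        X2 = X.copy()
        X2[:, 1] = 3.5 * X2[:, 1] - 7.0
        X2[:, 4] = -0.2 * X2[:, 4] + 1.0
        _, p2 = _univariate_stats(X2, y)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_constant_covariate_warns_not_raises(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = 1.0
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="constant"):
            res = sel.ewas(X, y)
        assert res.diagnostics["pvalues"][2] == 1.0

    def test_permutation_fdr_tracks_bh_selection_sizes(self):
        sizes_bh, sizes_perm = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X, y = signal_data(rng, 120, 20, [0, 1], r2=0.25)
            sizes_bh.append(len(sel.ewas(X, y, correction="bh").selected))
            sizes_perm.append(
                len(sel.ewas(X, y, correction="permutation",
                             random_state=seed).selected)
            )
        assert abs(np.mean(sizes_bh) - np.mean(sizes_perm)) <= 2.0

    def test_invalid_correction(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValidationError):
            sel.ewas(X, X[:, 0], correction="holmes")


class TestEWASMLR:
    def test_empty_stage1_gives_empty_result(self, rng):
        X = rng.standard_normal((200, 10))
        y = rng.standard_normal(200)
        res = sel.ewas_mlr(X, y, correction="bonferroni", level=1e-6)
        assert res.selected == ()
        assert not res.coef.any()

    def test_single_hit_retained_iff_univariate_significant(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = signal_data(rng, 300, 6, [2], r2=0.05)
            res = sel.ewas_mlr(X, y)
            stage1 = res.diagnostics["stage1_selected"]
            if stage1 == (2,):
                p_uni = res.diagnostics["stage1_pvalues"][2]
                assert (2 in res.selected) == (p_uni < 0.05)

    def test_collinearity_lowers_retention(self):
        # a near-duplicate of the true predictor inflates stage-2 variance
        kept_dup = kept_indep = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 150
            x0 = rng.standard_normal(n)
            dup = 0.995 * x0 + np.sqrt(1 - 0.995**2) * rng.standard_normal(n)
            noise = rng.standard_normal((n, 2))
            y = x0 + 2.0 * rng.standard_normal(n)
            X_dup = np.column_stack([x0, dup, noise])
            X_ind = np.column_stack([x0, rng.standard_normal(n), noise])
            kept_dup += 0 in sel.ewas_mlr(X_dup, y).selected
            kept_indep += 0 in sel.ewas_mlr(X_ind, y).selected
        assert kept_dup < kept_indep

    def test_aliased_columns_dropped_deterministically(self, rng):
        X = rng.standard_normal((100, 4))
        X[:, 3] = X[:, 0]  # exact alias, higher index must be dropped
        y = X[:, 0] + 0.1 * rng.standard_normal(100)
        with pytest.warns(UserWarning, match="aliased"):
            res = sel.ewas_mlr(X, y)
        assert 0 in res.selected
        assert 3 not in res.selected


class TestElasticNet:
    def test_pure_noise_median_empty(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 20))
            y = rng.standard_normal(80)
            sizes.append(len(sel.elastic_net(X, y, seed=seed).selected))
        assert np.median(sizes) == 0

    def test_noiseless_orthogonal_support_recovery(self):
        X = make_orthogonal_design(100, 30, seed=1)
        beta = np.zeros(30)
        beta[[2, 7, 11]] = 1.0
        res = sel.elastic_net(X, X @ beta, seed=0)
        assert res.selected == (2, 7, 11)

    def test_one_se_model_no_denser_than_minimum(self, rng):
        X, y = signal_data(rng, 150, 25, [0, 1, 2], r2=0.3)
        est = ElasticNetSelector(random_state=0).fit(X, y)
        assert len(est.selected_) <= est.size_at_min_

    def test_constant_outcome_empty(self, rng):
        X = rng.standard_normal((50, 5))
        res = sel.elastic_net(X, np.ones(50), seed=0)
        assert res.selected == ()


class TestSPLS:
    def test_pure_noise_mostly_empty(self):
        # sample size in study-like proportion to the grid so CV noise does
        # not hand one-component models spurious wins
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 30))
            y = rng.standard_normal(400)
            empty += sel.spls(X, y, seed=seed).selected == ()
        assert empty / 20 >= 0.8

    def test_eta_zero_keeps_all_weights(self, rng):
        from exposobench.selectors._spls import _pls_directions

        X = rng.standard_normal((60, 8))
        y = X @ rng.standard_normal(8) + rng.standard_normal(60)
        Xs = (X - X.mean(0)) / X.std(0)
        _, _, W = _pls_directions(Xs, y - y.mean(), 1, 0.0)
        assert np.count_nonzero(W[:, 0]) == 8

    def test_strong_predictor_always_selected(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = signal_data(rng, 1200, 20, [9], r2=0.5)
            assert 9 in sel.spls(X, y, seed=seed).selected

    def test_k_grid_must_include_zero(self, rng):
        X = rng.standard_normal((50, 5))
        with pytest.raises(ValidationError, match="K_grid"):
            sel.spls(X, X[:, 0], K_grid=(1, 2), seed=0)

    def test_noiseless_orthogonal_support_recovery(self):
        X = make_orthogonal_design(100, 30, seed=2)
        beta = np.zeros(30)
        beta[[5, 6, 20]] = 1.0
        res = sel.spls(X, X @ beta, seed=0)
        assert res.selected == (5, 6, 20)


class TestESS:
    CONFIG = dict(n_iter=3000, burn_in=600)

    def test_overwhelming_evidence_selected(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = signal_data(rng, 1200, 30, [13], r2=0.5)
            est = ESSSelector(mppi_threshold=0.9, random_state=seed,
                              **self.CONFIG).fit(X, y)
            assert est.mppi_[13] > 0.9
            assert 13 in est.selected_

    def test_null_calibrated_false_selection_rate(self, sigma50):
        # calibration and the null data share the exposure correlation, as
        # in the benchmark's k = 0 scenarios
        from exposobench.exposim import draw_exposome

        config = ESSConfig(n_iter=2000, burn_in=400)
        thr = sel.mppi_null_threshold(sigma50, 150, config, n_null_runs=40, seed=7)
        assert 0.0 <= thr <= 1.0
        any_hit = 0
        for seed in range(50):
            X = draw_exposome(sigma50, 150, seed=10000 + seed)
            y = np.random.default_rng(20000 + seed).standard_normal(150)
            res = sel.ess_select(X, y, config, mppi_threshold=thr, seed=seed)
            any_hit += bool(res.selected)
        assert any_hit / 50 <= 0.15

    def test_null_threshold_above_median(self, sigma50):
        # a 1 - 0.05/p quantile can never sit below the median of its pool
        config = ESSConfig(n_iter=800, burn_in=200)
        thr = sel.mppi_null_threshold(sigma50, 100, config, n_null_runs=3, seed=1)
        med = sel.mppi_null_threshold(sigma50, 100, config, n_null_runs=3, seed=1,
                                      quantile=0.5)
        assert thr >= med

    def test_prior_regime_rule(self):
        low = ESSConfig.for_k(3)
        assert (low.prior_model_size, low.prior_size_variance) == (3.0, 3.0)
        high = ESSConfig.for_k(10)
        assert (high.prior_model_size, high.prior_size_variance) == (12.0, 5.0)

    def test_null_quantile_level_for_study_p(self):
        assert 1.0 - 0.05 / 237 == pytest.approx(0.99978902953)

    def test_size_prior_is_finite_and_normalizable(self):
        logpmf = _size_prior_logpmf(237, 3.0, 3.0)
        assert np.all(np.isfinite(logpmf))
        # reassemble the size pmf: per-model prior times number of models
        from scipy.special import gammaln

        q = np.arange(238)
        lchoose = gammaln(238) - gammaln(q + 1) - gammaln(238 - q)
        total = np.exp(logpmf + lchoose).sum()
        assert total == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_orthogonal_support_recovery(self):
        X = make_orthogonal_design(100, 30, seed=3)
        beta = np.zeros(30)
        beta[[1, 8, 25]] = 1.0
        res = sel.ess_select(X, X @ beta, ESSConfig(**self.CONFIG),
                             mppi_threshold=0.5, seed=0)
        assert res.selected == (1, 8, 25)


class TestRidgeRefit:
    def test_empty_selection_zero_vector(self, rng):
        X = rng.standard_normal((30, 5))
        assert not ridge_refit(X, rng.standard_normal(30), []).any()

    def test_zero_penalty_matches_ols(self, rng):
        X = rng.standard_normal((60, 6))
        y = X[:, 0] - X[:, 2] + 0.1 * rng.standard_normal(60)
        coef = ridge_refit(X, y, [0, 1, 2], penalty=1e-12)
        design = np.column_stack([np.ones(60), X[:, :3]])
        ols = np.linalg.lstsq(design, y, rcond=None)[0][1:]
        np.testing.assert_allclose(coef[:3], ols, atol=1e-8)

    def test_orthonormal_closed_form_shrinkage(self):
        n = 100
        X = make_orthogonal_design(n, 4, seed=4)  # X'X = n I
        rng = np.random.default_rng(0)
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.standard_normal(n)
        lam = 25.0
        coef = ridge_refit(X, y, [0, 1, 2, 3], penalty=lam)
        ols = X.T @ (y - y.mean()) / n
        np.testing.assert_allclose(coef, ols * n / (n + lam), atol=1e-10)


class TestDSA:
    def test_pure_noise_median_empty(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 20))
            y = rng.standard_normal(80)
            sizes.append(len(sel.dsa(X, y, max_size=15, seed=seed).selected))
        assert np.median(sizes) == 0

    def test_noiseless_orthogonal_exact_pair(self):
        X = make_orthogonal_design(100, 30, seed=5)
        beta = np.zeros(30)
        beta[[4, 9]] = 1.0
        res = sel.dsa(X, X @ beta, seed=0)
        assert res.selected == (4, 9)

    def test_size_bound_respected(self, rng):
        X = rng.standard_normal((200, 50))
        y = X @ rng.standard_normal(50) + rng.standard_normal(200)
        res = sel.dsa(X, y, max_size=10, seed=0)
        assert res.n_selected <= 10

    def test_max_size_validation(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValidationError):
            sel.dsa(X, X[:, 0], max_size=18, seed=0)


@pytest.fixture(scope="module")
def noisy_data():
    rng = np.random.default_rng(99)
    X = rng.standard_normal((150, 15))
    beta = np.zeros(15)
    beta[[0, 7]] = 1.0
    y = X @ beta + rng.standard_normal(150)
    return X, y


class TestCommonContract:
    @pytest.mark.parametrize("cls", ALL_SELECTORS, ids=lambda c: c.method_name)
    def test_result_support_matches_selection(self, cls, noisy_data):
        X, y = noisy_data
        params = {"n_iter": 1500, "burn_in": 300} if cls is ESSSelector else {}
        if cls is DSASelector:
            params["max_size"] = 10
        res = cls(random_state=0, **params).fit(X, y).to_result()
        assert res.coef.shape == (15,)
        assert set(np.flatnonzero(res.coef)) <= set(res.selected)

    @pytest.mark.parametrize("cls", ALL_SELECTORS, ids=lambda c: c.method_name)
    def test_sklearn_clone_and_params(self, cls):
        est = cls()
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    @pytest.mark.parametrize("cls", ALL_SELECTORS, ids=lambda c: c.method_name)
    def test_noiseless_orthogonal_support_recovery_all_methods(self, cls):
        X = make_orthogonal_design(120, 30, seed=6)
        beta = np.zeros(30)
        truth = (3, 14, 22)
        beta[list(truth)] = 1.0
        params = {"n_iter": 3000, "burn_in": 600, "mppi_threshold": 0.5} \
            if cls is ESSSelector else {}
        est = cls(random_state=0, **params).fit(X, X @ beta)
        assert est.selected_ == truth

    def test_registry_roundtrip(self):
        est = sel.make_selector("DSA", max_size=12)
        assert isinstance(est, DSASelector)
        assert est.max_size == 12
        with pytest.raises(KeyError):
            sel.make_selector("nonexistent")

    def test_registry_accepts_external_selector(self):
        class Dummy(sel.BaseSelector):
            method_name = "dummy-test"

            def _fit(self, X, y):
                self.selected_ = ()
                self.coef_ = np.zeros(X.shape[1])
                self.intercept_ = 0.0
                self.diagnostics_ = {}

        sel.register_selector(Dummy)
        try:
            assert isinstance(sel.make_selector("dummy-test"), Dummy)
        finally:
            del sel.SELECTOR_REGISTRY["dummy-test"]
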