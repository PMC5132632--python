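"""Performance metrics: classical, bias, alternative, and extended protocol."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exposobench import exposim as ex
from exposobench import perfmetrics as pm
from exposobench.selectors import SelectionResult


def random_corr(rng, p):
    Z = rng.standard_normal((p + 5, p))
    C = np.corrcoef(Z, rowvar=False)
    return C


class TestClassificationMetrics:
    def test_perfect_selection(self):
        sens, spec, fdp = pm.classification_metrics(range(5), range(5), 237)
        assert (sens, spec, fdp) == (1.0, 1.0, 0.0)

    def test_empty_selection_fdp_zero(self):
        sens, spec, fdp = pm.classification_metrics({0, 1, 2}, set(), 10)
        assert fdp == 0.0
        assert sens == 0.0
        assert spec == 1.0

    def test_hand_count(self):
        sens, spec, fdp = pm.classification_metrics({0, 1}, {1, 2}, 5)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(2 / 3)
        assert fdp == pytest.approx(0.5)

    def test_k0_sensitivity_na(self):
        sens, spec, fdp = pm.classification_metrics(set(), {1}, 5)
        assert math.isnan(sens)
        assert spec == pytest.approx(4 / 5)

    def test_exhaustive_confusion_matrix_oracle(self):
        # all (A, B) subset pairs for small p against a brute-force oracle
        p = 5
        universe = list(range(p))
        subsets = [frozenset(c) for r in range(p + 1)
                   for c in itertools.combinations(universe, r)]
        for A in subsets:
            for B in subsets:
                sens, spec, fdp = pm.classification_metrics(A, B, p)
                tp = len(A & B)
                fp = len(B - A)
                tn = len(set(universe) - A - B)
                if A:
                    assert sens == pytest.approx(tp / len(A))
                else:
                    assert math.isnan(sens)
                if len(A) < p:
                    assert spec == pytest.approx(tn / (p - len(A)))
                else:
                    assert math.isnan(spec)
                assert fdp == pytest.approx(fp / len(B) if B else 0.0)


class TestMeanAbsoluteBias:
    def test_exact_estimate(self):
        assert pm.mean_absolute_bias([1, 0, 2], [1, 0, 2]) == 0.0

    def test_hand_computed_subsets(self):
        bt = np.array([1.0, 0.0, 0.0])
        bh = np.array([0.4, 0.3, 0.0])
        assert pm.mean_absolute_bias(bt, bh, "all") == pytest.approx(0.3)
        assert pm.mean_absolute_bias(bt, bh, "true") == pytest.approx(0.6)
        assert pm.mean_absolute_bias(bt, bh, "null") == pytest.approx(0.15)

    def test_empty_subset_na(self):
        assert math.isnan(pm.mean_absolute_bias([0.0, 0.0], [1.0, 0.0], "true"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 10**6))
    def test_decomposition_identity(self, p, seed):
        rng = np.random.default_rng(seed)
        bt = np.where(rng.random(p) < 0.3, rng.standard_normal(p), 0.0)
        bh = rng.standard_normal(p)
        k = int(np.count_nonzero(bt))
        mab_all = pm.mean_absolute_bias(bt, bh, "all")
        mab_true = pm.mean_absolute_bias(bt, bh, "true") if k else 0.0
        mab_null = pm.mean_absolute_bias(bt, bh, "null") if k < p else 0.0
        assert mab_all == pytest.approx((k * mab_true + (p - k) * mab_null) / p)


class TestAltMetrics:
    def test_self_selection(self):
        C = np.eye(4)
        assert pm.alt_metrics({1, 2}, {1, 2}, C) == (1.0, 0.0)

    def test_single_pair_formula(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        alt_sens, alt_fdp = pm.alt_metrics({0}, {1}, C)
        assert alt_sens == pytest.approx(0.8)
        assert alt_fdp == pytest.approx(0.2)

    def test_empty_selection_convention(self):
        assert pm.alt_metrics({0}, set(), np.eye(3)) == (0.0, 0.0)

    def test_identity_corr_reduces_to_classical(self, rng):
        # with uncorrelated covariates the alt metrics equal the classical
        # ones for any disjoint-or-overlapping pair of sets
        p = 8
        for _ in range(50):
            A = set(rng.choice(p, rng.integers(1, 4), replace=False).tolist())
            B = set(rng.choice(p, rng.integers(0, 5), replace=False).tolist())
            sens, _, fdp = pm.classification_metrics(A, B, p)
            alt_sens, alt_fdp = pm.alt_metrics(A, B, np.eye(p))
            if B:
                assert alt_sens == pytest.approx(sens)
                assert alt_fdp == pytest.approx(fdp)

    def test_dominates_classical_on_random_triples(self, rng):
        # AltSens >= sensitivity and AltFDP <= FDP, 1000 random triples
        for i in range(1000):
            p = int(rng.integers(3, 12))
            C = random_corr(rng, p)
            A = set(rng.choice(p, int(rng.integers(1, p)), replace=False).tolist())
            B = set(rng.choice(p, int(rng.integers(1, p)), replace=False).tolist())
            sens, _, fdp = pm.classification_metrics(A, B, p)
            alt_sens, alt_fdp = pm.alt_metrics(A, B, C)
            assert alt_sens >= sens - 1e-12
            assert alt_fdp <= fdp + 1e-12


class TestExtendedSelection:
    def test_no_strong_partner_is_identity(self):
        C = np.eye(5)
        assert pm.extended_selection({1, 3}, C, 0.8) == (1, 3)

    def test_threshold_pulls_in_partner(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.95
        assert pm.extended_selection({0}, C, 0.9) == (0, 1)

    def test_monotone_in_alpha(self, rng):
        p = 12
        C = random_corr(rng, p)
        B = {0, 5}
        prev = None
        for alpha in (0.9, 0.8, 0.7, 0.6):
            cur = set(pm.extended_selection(B, C, alpha))
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_empty_selection_stays_empty(self):
        assert pm.extended_selection(set(), np.eye(4), 0.6) == ()


class TestScoreRun:
    def _dataset(self, rng, p=20, k=3, n=50):
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        idx = tuple(range(k))
        beta[list(idx)] = 1.0
        y = X @ beta + rng.standard_normal(n)
        return ex.SimulatedDataset(X=X, y=y, true_idx=idx, beta=beta,
                                   sigma2=1.0, seed=0)

    def test_oracle_result_is_perfect(self, rng):
        ds = self._dataset(rng)
        res = SelectionResult("oracle", ds.true_idx, ds.beta)
        rec = pm.score_run(ds, res)
        assert rec.sensitivity == 1.0
        assert rec.fdp == 0.0
        assert rec.mab_all == rec.mab_true == rec.mab_null == 0.0
        assert rec.alt_sens == pytest.approx(1.0)

    def test_k0_metrics_na(self, rng):
        ds = self._dataset(rng, k=0)
        res = SelectionResult("m", (1, 2), np.zeros(20))
        rec = pm.score_run(ds, res)
        assert math.isnan(rec.sensitivity) and math.isnan(rec.fdp)
        assert math.isnan(rec.alt_sens) and math.isnan(rec.n_b_over_k)
        assert rec.specificity == pytest.approx(18 / 20)

    def test_record_invariants_on_random_runs(self, rng):
        for i in range(100):
            ds = self._dataset(rng, k=int(rng.integers(1, 5)))
            sel = tuple(
                int(j) for j in rng.choice(20, int(rng.integers(0, 8)), replace=False)
            )
            coef = np.zeros(20)
            coef[list(sel)] = rng.standard_normal(len(sel))
            rec = pm.score_run(ds, SelectionResult("m", sel, coef))
            assert rec.alt_sens >= rec.sensitivity - 1e-12
            assert rec.alt_fdp <= rec.fdp + 1e-12
            k, p = ds.k, ds.p
            assert rec.mab_all == pytest.approx(
                (k * rec.mab_true + (p - k) * rec.mab_null) / p
            )

    def test_sigma_corr_source(self, rng, sigma50):
        spec = ex.scenario(1, 2, n=60, p=50)
        ds = ex.simulate_run(spec, sigma50, seed=0)
        res = SelectionResult("m", ds.true_idx, ds.beta)
        rec = pm.score_run(ds, res, corr_source="sigma", sigma=sigma50.values)
        assert rec.alt_sens == pytest.approx(1.0)

    def test_metrics_are_pure(self, rng):
        ds = self._dataset(rng)
        res = SelectionResult("m", (0, 5), np.zeros(20))
        a = pm.score_run(ds, res)
        b = pm.score_run(ds, res)
        assert a == b
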