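"""Environment-wide association study (EWAS) selectors.

EWAS fits one univariate ordinary-least-squares regression (with intercept)
per covariate and selects those whose two-sided p-value survives a
multiplicity correction at a chosen level (Benjamini-Hochberg FDR 5% as the
benchmark; Benjamini-Yekutieli, Bonferroni, a permutation-based FDR, and no
correction as sensitivity analyses).  EWAS-MLR adds a second stage: the
stage-1 hits enter one multiple linear regression and are retained when
their two-sided p-value there is below 5%.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .._rng import substream
from ..errors import ValidationError
from ._base import BaseSelector

CORRECTIONS = ("bh", "by", "bonferroni", "permutation", "none")


def _univariate_stats(X: np.ndarray, y: np.ndarray):
    """Vectorized per-covariate OLS slope and two-sided p-value.

    Equivalent to fitting ``y ~ 1 + X_j`` for each j: the t statistic of the
    slope equals r * sqrt((n-2) / (1-r^2)) with r the sample correlation.
    Constant covariates get slope 0 and p-value 1 (with a warning).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    ssy = float(yc @ yc)
    constant = ssx <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant covariate(s); p-value set to 1",
            stacklevel=3,
        )
    ssx_safe = np.where(constant, 1.0, ssx)
    sxy = Xc.T @ yc
    slope = sxy / ssx_safe
    if ssy <= 0:
        r2 = np.zeros_like(slope)
    else:
        r2 = np.clip(sxy**2 / (ssx_safe * ssy), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        t2 = r2 * (n - 2) / np.clip(1.0 - r2, 1e-300, None)
    pvals = 2.0 * stats.t.sf(np.sqrt(t2), df=n - 2)
    pvals[constant] = 1.0
    slope[constant] = 0.0
    return slope, np.clip(pvals, 0.0, 1.0)


def _permutation_fdr_select(
    X: np.ndarray, y: np.ndarray, pvals: np.ndarray, level: float,
    n_permutations: int, seed: int,
) -> np.ndarray:
    """Permutation-based FDR: estimate, for candidate thresholds t, the
    expected null count of p-values <= t from outcome permutations, and pick
    the largest t whose estimated FDR stays below ``level``.
    """
    n, p = X.shape
    rng = substream(seed, "permutation-fdr")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sx_safe = np.where(sx > 0, sx, 1.0)
    Xs = Xc / sx_safe
    null_p = np.empty((n_permutations, p))
    for b in range(n_permutations):
        yp = y[rng.permutation(n)]
        yc = yp - yp.mean()
        sy = np.sqrt(yc @ yc)
        r = Xs.T @ (yc / sy) if sy > 0 else np.zeros(p)
        r2 = np.clip(r**2, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            t2 = r2 * (n - 2) / np.clip(1.0 - r2, 1e-300, None)
        null_p[b] = 2.0 * stats.t.sf(np.sqrt(t2), df=n - 2)
    null_sorted = np.sort(null_p.ravel())
    thresholds = np.sort(pvals)
    obs_counts = np.arange(1, p + 1)
    null_counts = np.searchsorted(null_sorted, thresholds, side="right") / n_permutations
    fdr = null_counts / obs_counts
    ok = np.flatnonzero(fdr <= level)
    if ok.size == 0:
        return np.zeros(p, dtype=bool)
    t_star = thresholds[ok[-1]]
    return pvals <= t_star


def _apply_correction(pvals, correction, level, X=None, y=None, seed=0, n_permutations=100):
    if correction in ("bh", "by"):
        reject, *_ = multipletests(pvals, alpha=level, method={"bh": "fdr_bh", "by": "fdr_by"}[correction])
        return reject
    if correction == "bonferroni":
        reject, *_ = multipletests(pvals, alpha=level, method="bonferroni")
        return reject
    if correction == "none":
        return pvals < level
    if correction == "permutation":
        return _permutation_fdr_select(X, y, pvals, level, n_permutations, seed)
    raise ValidationError(f"unknown correction {correction!r} (expected one of {CORRECTIONS})")


class EWASSelector(BaseSelector):
    """Univariate screening with multiplicity correction.

    Parameters
    ----------
    correction : {"bh", "by", "bonferroni", "permutation", "none"}
        Multiple-testing rule applied to the per-covariate p-values.
    level : float
        Target FDR / FWER / per-test level, default 5%.
    n_permutations : int
        Outcome permutations for the permutation-based FDR.
    random_state : int
        Seed for the permutation null (ignored by other corrections).
    """

    method_name = "EWAS"

    def __init__(self, correction="bh", level=0.05, n_permutations=100, random_state=0):
        self.correction = correction
        self.level = level
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _fit(self, X, y):
        if not 0.0 < self.level < 1.0:
            raise ValidationError("level must lie in (0, 1)")
        slope, pvals = _univariate_stats(X, y)
        reject = _apply_correction(
            pvals, self.correction, self.level,
            X=X, y=y, seed=self.random_state, n_permutations=self.n_permutations,
        )
        self.pvalues_ = pvals
        self.selected_ = tuple(int(j) for j in np.flatnonzero(reject))
        coef = np.zeros(X.shape[1])
        coef[list(self.selected_)] = slope[list(self.selected_)]
        self.coef_ = coef
        self.intercept_ = float(y.mean() - X.mean(axis=0) @ coef)
        self.diagnostics_ = {
            "pvalues": pvals,
            "univariate_slopes": slope,
            "correction": self.correction,
            "level": self.level,
        }


def _drop_aliased(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Deterministically keep a maximal independent column subset (lowest
    indices first), for a singular second-stage design."""
    keep: list[int] = []
    Q = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        v = X[:, j] - X[:, j].mean()
        r = v - Q @ (Q.T @ v)
        nrm = np.linalg.norm(r)
        if nrm > tol * max(1.0, np.linalg.norm(v)):
            keep.append(j)
            Q = np.hstack([Q, (r / nrm)[:, None]])
    return np.asarray(keep, dtype=int)


class EWASMLRSelector(BaseSelector):
    """EWAS followed by a multiple-linear-regression confirmation stage.

    Stage 1 is :class:`EWASSelector`; its hits enter one multiple OLS fit
    and are retained when their two-sided p-value there is below
    ``stage2_level`` (5%).  Coefficients come from the stage-2 fit.
    """

    method_name = "EWAS-MLR"

    def __init__(self, correction="bh", level=0.05, stage2_level=0.05,
                 n_permutations=100, random_state=0):
        self.correction = correction
        self.level = level
        self.stage2_level = stage2_level
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _fit(self, X, y):
        stage1 = EWASSelector(
            correction=self.correction, level=self.level,
            n_permutations=self.n_permutations, random_state=self.random_state,
        ).fit(X, y)
        hits = np.asarray(stage1.selected_, dtype=int)
        p = X.shape[1]
        coef = np.zeros(p)
        if hits.size == 0:
            self.selected_ = ()
            self.coef_ = coef
            self.intercept_ = float(y.mean())
            self.diagnostics_ = {"stage1_selected": (), "stage2_pvalues": {}}
            return
        sub = X[:, hits]
        indep = _drop_aliased(sub)
        if indep.size < hits.size:
            warnings.warn(
                f"dropped {hits.size - indep.size} aliased column(s) in the "
                "second-stage regression", stacklevel=2,
            )
        hits = hits[indep]
        sub = X[:, hits]
        n, q = sub.shape
        design = np.hstack([np.ones((n, 1)), sub])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = n - q - 1
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.clip(np.diag(cov)[1:], 1e-300, None))
        tvals = beta[1:] / se
        pvals2 = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
        retained = pvals2 < self.stage2_level
        self.selected_ = tuple(int(j) for j in hits[retained])
        coef[hits[retained]] = beta[1:][retained]
        self.coef_ = coef
        self.intercept_ = float(beta[0])
        self.diagnostics_ = {
            "stage1_selected": tuple(int(j) for j in stage1.selected_),
            "stage1_pvalues": stage1.pvalues_,
            "stage2_pvalues": dict(zip((int(j) for j in hits), pvals2)),
        }
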