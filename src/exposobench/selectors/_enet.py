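"""Elastic net with cross-validated one-standard-error model choice.

The grid spans the lasso/ridge mixing proportion and an overall penalty
path; for each grid point the 10-fold cross-validated prediction RMSE and
its standard error across folds are computed.  To prevent over-fitting the
chosen point is the *sparsest* model (fewest nonzero coefficients) among
those whose CV RMSE lies within one standard error of the minimum.
Covariates are standardized internally; coefficients are reported on the
original scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path as _enet_path
from sklearn.model_selection import KFold


def enet_path(*args, **kwargs):
    # coordinate descent may not fully converge at the smallest penalties on
    # the path; those extreme grid points never win the 1-SE choice, so the
    # warning is noise here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return _enet_path(*args, **kwargs)

from .._rng import child_seed
from ..errors import ValidationError
from ._base import BaseSelector, _standardize

DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


def _alpha_grid(Xs, yc, l1_ratio, n_alphas, eps=1e-3):
    n = Xs.shape[0]
    alpha_max = np.max(np.abs(Xs.T @ yc)) / (n * l1_ratio)
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


class ElasticNetSelector(BaseSelector):
    """Elastic-net variable selection with the 1-SE rule.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds (10).
    l1_ratios : sequence of float
        Mixing proportions between lasso (1) and ridge (0) penalties.
    n_alphas : int
        Log-spaced overall penalties per mixing proportion.
    random_state : int
        Seed for the fold partition (shared across the whole grid).
    """

    method_name = "ENET"

    def __init__(self, n_folds=10, l1_ratios=DEFAULT_L1_RATIOS, n_alphas=100,
                 random_state=0):
        self.n_folds = n_folds
        self.l1_ratios = l1_ratios
        self.n_alphas = n_alphas
        self.random_state = random_state

    def _fit(self, X, y):
        n, p = X.shape
        if n <= self.n_folds:
            raise ValidationError("need more samples than folds")
        Xs, xm, sd = _standardize(X)
        ym = float(y.mean())
        yc = y - ym
        if np.allclose(y, y[0]):
            self.selected_ = ()
            self.coef_ = np.zeros(p)
            self.intercept_ = ym
            self.diagnostics_ = {"note": "constant outcome; empty selection"}
            return

        l1_ratios = list(self.l1_ratios)
        folds = list(
            KFold(self.n_folds, shuffle=True,
                  random_state=child_seed(self.random_state, "enet-folds")).split(Xs)
        )
        n_l1 = len(l1_ratios)
        rmse = np.empty((n_l1, self.n_alphas, self.n_folds))
        grids = []
        for a, l1 in enumerate(l1_ratios):
            alphas = _alpha_grid(Xs, yc, l1, self.n_alphas)
            grids.append(alphas)
            for f, (tr, te) in enumerate(folds):
                ytr = yc[tr]
                off = ytr.mean()
                _, coefs, _ = enet_path(
                    Xs[tr], ytr - off, l1_ratio=l1, alphas=alphas
                )
                pred = Xs[te] @ coefs + off
                err = pred - yc[te][:, None]
                rmse[a, :, f] = np.sqrt(np.mean(err**2, axis=0))

        mean_rmse = rmse.mean(axis=2)
        se_rmse = rmse.std(axis=2, ddof=1) / np.sqrt(self.n_folds)
        a_min, j_min = np.unravel_index(np.argmin(mean_rmse), mean_rmse.shape)
        threshold = mean_rmse[a_min, j_min] + se_rmse[a_min, j_min]
        admissible = mean_rmse <= threshold

        # count nonzeros of the full-data fit at every admissible grid point
        nnz = np.full(mean_rmse.shape, np.iinfo(np.int32).max, dtype=np.int64)
        full_coefs = {}
        for a, l1 in enumerate(l1_ratios):
            if not admissible[a].any():
                continue
            _, coefs, _ = enet_path(Xs, yc, l1_ratio=l1, alphas=grids[a])
            full_coefs[a] = coefs  # p x n_alphas
            nnz[a] = np.count_nonzero(coefs, axis=0)
        nnz_adm = np.where(admissible, nnz, np.iinfo(np.int32).max)
        # sparsest admissible; ties -> stronger penalty (lower alpha index),
        # then larger mixing proportion
        best = np.argwhere(nnz_adm == nnz_adm.min())
        best = sorted((int(a), int(j)) for a, j in best)
        a_star, j_star = min(best, key=lambda t: (t[1], -t[0]))

        coef_std = full_coefs[a_star][:, j_star]
        coef = coef_std / sd
        self.selected_ = tuple(int(j) for j in np.flatnonzero(coef_std))
        out = np.zeros(p)
        out[list(self.selected_)] = coef[list(self.selected_)]
        self.coef_ = out
        self.intercept_ = ym - float(xm @ out)
        self.diagnostics_ = {
            "l1_ratio": float(l1_ratios[a_star]),
            "alpha": float(grids[a_star][j_star]),
            "cv_rmse": float(mean_rmse[a_star, j_star]),
            "cv_rmse_min": float(mean_rmse[a_min, j_min]),
            "cv_rmse_se_at_min": float(se_rmse[a_min, j_min]),
            "n_nonzero_at_min": int(np.count_nonzero(full_coefs[a_star][:, j_star]))
            if a_star in full_coefs else None,
        }
        # the 1-SE model can never be denser than the RMSE-minimizing model
        self.size_at_min_ = int(nnz[a_min, j_min]) if a_min in full_coefs else None
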