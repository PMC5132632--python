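"""Sparse partial least squares (sPLS) regression selector.

PLS builds components iteratively, each a linear combination of the
covariates chosen to capture as much of the remaining covariance between
predictors and outcome as possible.  Sparsity comes from soft-thresholding
the direction vector: weights with absolute value below a fraction eta of
the largest are shrunk to zero.  Variables with a nonzero weight on any
retained component form the selected set; the reported coefficients come
from a plain PLS refit on that set, regressing the outcome on the K
components and mapping back to the original variables.  K and eta are
calibrated by 5-fold cross-validated RMSE, with K = 0 (the intercept-only
model) included in the grid so a pure-noise outcome can yield an empty
selection.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import KFold

from .._rng import child_seed
from ..errors import ValidationError
from ._base import BaseSelector, _standardize

DEFAULT_K_GRID = (0, 1, 2, 3, 4, 5)
DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.0, 0.91, 0.1), 2))


def _soft_threshold(w: np.ndarray, eta: float) -> np.ndarray:
    thr = eta * np.max(np.abs(w))
    return np.sign(w) * np.clip(np.abs(w) - thr, 0.0, None)


def _pls_directions(Xs: np.ndarray, yc: np.ndarray, K: int, eta: float):
    """Up to K soft-thresholded direction vectors and component machinery.

    Returns (R, T, W): T = Xs @ R are the component scores and W the raw
    sparse direction vectors (their supports define the selected set).
    """
    n, p = Xs.shape
    Xr = Xs.copy()
    yr = yc.copy()
    rs, ws, ts, loadings = [], [], [], []
    for _ in range(K):
        w = Xr.T @ yr
        if not np.any(w):
            break
        w = _soft_threshold(w, eta)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            break
        w = w / nrm
        t = Xr @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        # express the score as a linear map of the undeflated covariates
        r = w - sum(r_j * float(p_j @ w) for r_j, p_j in zip(rs, loadings))
        loading = Xr.T @ t / tt
        rs.append(r)
        ws.append(w)
        ts.append(t)
        loadings.append(loading)
        Xr = Xr - np.outer(t, loading)
        yr = yr - t * (float(t @ yr) / tt)
    if not ts:
        return np.zeros((p, 0)), np.zeros((n, 0)), np.zeros((p, 0))
    return np.column_stack(rs), np.column_stack(ts), np.column_stack(ws)


def _spls_coefs(Xs: np.ndarray, yc: np.ndarray, K_list, eta: float) -> dict[int, np.ndarray]:
    """Standardized-scale coefficient vector for each K in K_list.

    The sparse directions fix the selected support; coefficients come from
    a dense PLS refit restricted to that support (reference-implementation
    behavior), so they are exactly zero elsewhere.
    """
    p = Xs.shape[1]
    K_max = max(K_list)
    out = {}
    supports = {}
    if 0 in K_list:
        out[0] = np.zeros(p)
        supports[0] = np.empty(0, dtype=int)
    if K_max == 0:
        return out, supports
    _, _, W = _pls_directions(Xs, yc, K_max, eta)
    for K in K_list:
        if K == 0:
            continue
        Ku = min(K, W.shape[1])
        coef = np.zeros(p)
        support = np.empty(0, dtype=int)
        if Ku > 0:
            support = np.flatnonzero(np.any(W[:, :Ku] != 0, axis=1))
            Ku = min(Ku, support.size)
            R, T, _ = _pls_directions(Xs[:, support], yc, Ku, 0.0)
            if T.shape[1] > 0:
                gamma, *_ = np.linalg.lstsq(T, yc, rcond=None)
                coef[support] = R @ gamma
        out[K] = coef
        supports[K] = support
    return out, supports


class SPLSSelector(BaseSelector):
    """Sparse PLS with CV-calibrated component count and threshold.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds (5).
    K_grid : sequence of int
        Component counts to try; must include 0 (intercept-only model).
    eta_grid : sequence of float
        Soft-threshold fractions in [0, 1).
    random_state : int
        Seed for the fold partition.
    """

    method_name = "sPLS"

    def __init__(self, n_folds=5, K_grid=DEFAULT_K_GRID, eta_grid=DEFAULT_ETA_GRID,
                 random_state=0):
        self.n_folds = n_folds
        self.K_grid = K_grid
        self.eta_grid = eta_grid
        self.random_state = random_state

    def _fit(self, X, y):
        n, p = X.shape
        K_grid = sorted(int(k) for k in self.K_grid)
        if 0 not in K_grid:
            raise ValidationError("K_grid must include 0 (the empty model)")
        if any(not 0.0 <= e < 1.0 for e in self.eta_grid):
            raise ValidationError("eta_grid values must lie in [0, 1)")
        if max(K_grid) >= min(n - 1, p):
            warnings.warn("K grid truncated to the design rank", stacklevel=2)
            K_grid = [k for k in K_grid if k < min(n - 1, p)]

        Xs, xm, sd = _standardize(X)
        ym = float(y.mean())
        yc = y - ym

        folds = list(
            KFold(self.n_folds, shuffle=True,
                  random_state=child_seed(self.random_state, "spls-folds")).split(Xs)
        )
        etas = list(self.eta_grid)
        sse = np.zeros((len(etas), len(K_grid)))
        count = np.zeros_like(sse)
        for tr, te in folds:
            Xtr, ytr = Xs[tr], yc[tr]
            off = ytr.mean()
            for e, eta in enumerate(etas):
                coefs, _ = _spls_coefs(Xtr, ytr - off, K_grid, eta)
                for ki, K in enumerate(K_grid):
                    pred = Xs[te] @ coefs[K] + off
                    resid = yc[te] - pred
                    sse[e, ki] += float(resid @ resid)
                    count[e, ki] += len(te)
        rmse = np.sqrt(sse / count)
        # minimize CV RMSE; ties -> fewer components, then stronger threshold
        order = sorted(
            (rmse[e, ki], K_grid[ki], -etas[e], e, ki)
            for e in range(len(etas)) for ki in range(len(K_grid))
        )
        _, K_star, _, e_star, ki_star = order[0]
        eta_star = etas[e_star]

        coefs, supports = _spls_coefs(Xs, yc, [K_star], eta_star)
        coef_std = coefs[K_star]
        selected = tuple(int(j) for j in supports[K_star])
        coef = np.zeros(p)
        coef[list(selected)] = (coef_std / sd)[list(selected)]
        self.selected_ = selected
        self.coef_ = coef
        self.intercept_ = ym - float(xm @ coef)
        self.diagnostics_ = {"K": int(K_star), "eta": float(eta_star),
                             "cv_rmse": float(rmse[e_star, ki_star])}
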