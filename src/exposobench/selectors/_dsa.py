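"""Deletion / substitution / addition (DSA) model search.

A greedy search over linear main-effects models: starting from the
intercept-only model, candidate moves remove a term, replace one term with
another, or add a term.  Moves are scored by residual sum of squares; the
best model found for each size (up to ``max_size``) is recorded, and the
final size is the one minimizing 5-fold cross-validated RMSE, with the
coefficients refit by ordinary least squares on the full data.  No
polynomial or interaction terms are considered.

All move evaluations run on the Gram matrix of the centered design, so a
full search at a few hundred covariates stays fast: for a current model S,
adding j changes the RSS by the squared partial correlation term
r_j^2 / d_j, with r the residual covariance and d the residual variance of
column j given S, all computed vectorized over j.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.model_selection import KFold

from .._rng import child_seed
from ..errors import ValidationError
from ._base import BaseSelector

_RIDGE_EPS = 1e-10


class _GramRSS:
    """RSS machinery on a centered design's Gram matrix."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.G = Xc.T @ Xc
        self.c = Xc.T @ yc
        self.yty = float(yc @ yc)
        self.diag = np.diag(self.G).copy()
        self.p = X.shape[1]

    def _chol(self, S: list[int]):
        Gss = self.G[np.ix_(S, S)] + _RIDGE_EPS * np.eye(len(S))
        return np.linalg.cholesky(Gss)

    def rss(self, S) -> float:
        S = list(S)
        if not S:
            return self.yty
        L = self._chol(S)
        z = solve_triangular(L, self.c[S], lower=True)
        return max(self.yty - float(z @ z), 0.0)

    def best_addition(self, S) -> tuple[int, float] | None:
        """Best single-column addition to S: (column, new RSS)."""
        S = list(S)
        free = np.setdiff1d(np.arange(self.p), S, assume_unique=False)
        if free.size == 0:
            return None
        if not S:
            d = self.diag[free]
            r = self.c[free]
            base = self.yty
        else:
            L = self._chol(S)
            B = solve_triangular(L, self.G[np.ix_(S, free)], lower=True)
            z = solve_triangular(L, self.c[S], lower=True)
            base = max(self.yty - float(z @ z), 0.0)
            d = self.diag[free] - np.einsum("ij,ij->j", B, B)
            r = self.c[free] - B.T @ z
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(d > 1e-9 * np.maximum(self.diag[free], 1.0), r**2 / d, -np.inf)
        if not np.isfinite(gain).any():
            return None
        j = int(free[int(np.argmax(gain))])
        return j, max(base - float(np.max(gain)), 0.0)


class DSASelector(BaseSelector):
    """DSA variable selection with CV-chosen model size.

    Parameters
    ----------
    max_size : int
        Largest model size explored (40).
    n_folds : int
        Folds for the final cross-validated size choice (5).
    random_state : int
        Seed for the fold partition (the search itself is deterministic).
    """

    method_name = "DSA"

    def __init__(self, max_size=40, n_folds=5, random_state=0):
        self.max_size = max_size
        self.n_folds = n_folds
        self.random_state = random_state

    def _search(self, gram: _GramRSS) -> dict[int, tuple[tuple, float]]:
        """Greedy DSA pass: best model found per size, scored by RSS.

        Ties between equal-RSS moves resolve to the lowest variable index
        (the candidate orderings below are index-sorted and strict
        improvement is required to switch).
        """
        p = gram.p
        max_size = min(self.max_size, p)
        best: dict[int, tuple[tuple, float]] = {0: ((), gram.yty)}
        current: tuple = ()
        rss_cur = gram.yty
        tol = 1e-12 * max(gram.yty, 1.0)
        while len(current) < max_size:
            s = len(current)
            # deletion: does dropping one term beat the best smaller model?
            if s >= 1:
                del_cands = [tuple(v for v in current if v != i) for i in current]
                del_rss = [gram.rss(S) for S in del_cands]
                i_best = int(np.argmin(del_rss))
                if del_rss[i_best] < best[s - 1][1] - tol:
                    current, rss_cur = del_cands[i_best], del_rss[i_best]
                    best[s - 1] = (current, rss_cur)
                    continue
            # substitution: replace one term, stay at the same size
            if s >= 1:
                sub_best = None
                for i in current:
                    S_minus = [v for v in current if v != i]
                    add = gram.best_addition(S_minus)
                    if add is not None and (sub_best is None or add[1] < sub_best[2]):
                        sub_best = (S_minus, add[0], add[1])
                if sub_best is not None and sub_best[2] < best[s][1] - tol:
                    current = tuple(sorted(sub_best[0] + [sub_best[1]]))
                    rss_cur = sub_best[2]
                    best[s] = (current, rss_cur)
                    continue
            # addition
            add = gram.best_addition(current)
            if add is None:
                break
            current = tuple(sorted(current + (add[0],)))
            rss_cur = add[1]
            if s + 1 not in best or rss_cur < best[s + 1][1] - tol:
                best[s + 1] = (current, rss_cur)
        return best

    def _fit(self, X, y):
        n, p = X.shape
        if not self.max_size < n - self.n_folds:
            raise ValidationError("max_size must be smaller than n minus the fold count")
        folds = list(
            KFold(self.n_folds, shuffle=True,
                  random_state=child_seed(self.random_state, "dsa-folds")).split(X)
        )
        # the search runs inside every training fold: the per-size models
        # scored on the held-out data were chosen without seeing it
        sse = {}
        for tr, te in folds:
            best_f = self._search(_GramRSS(X[tr], y[tr]))
            max_avail = max(best_f)
            for size in range(self.max_size + 1):
                S = list(best_f[min(size, max_avail)][0])
                if S:
                    design = np.hstack([np.ones((len(tr), 1)), X[np.ix_(tr, S)]])
                    beta, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
                    pred = np.hstack([np.ones((len(te), 1)), X[np.ix_(te, S)]]) @ beta
                else:
                    pred = np.full(len(te), y[tr].mean())
                sse[size] = sse.get(size, 0.0) + float(np.sum((y[te] - pred) ** 2))
        cv_rmse = {size: np.sqrt(v / n) for size, v in sse.items()}
        # minimize CV RMSE; near-ties (within a small relative tolerance,
        # e.g. the noiseless case where several sizes fit exactly) favor the
        # smaller model
        cv_min = min(cv_rmse.values())
        tol = 1e-8 * max(cv_min, float(np.std(y)), 1e-12)
        size_star = min(s for s, v in cv_rmse.items() if v <= cv_min + tol)

        best = self._search(_GramRSS(X, y))
        size_star = min(size_star, max(best))
        sizes = sorted(best)
        S = list(best[size_star][0])
        coef = np.zeros(p)
        if S:
            design = np.hstack([np.ones((n, 1)), X[:, S]])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            coef[S] = beta[1:]
            intercept = float(beta[0])
        else:
            intercept = float(y.mean())
        self.selected_ = tuple(int(j) for j in S)
        self.coef_ = coef
        self.intercept_ = intercept
        self.diagnostics_ = {
            "size": int(size_star),
            "cv_rmse_by_size": {int(s): float(v) for s, v in cv_rmse.items()},
            "rss_by_size": {int(s): float(best[s][1]) for s in sizes},
        }
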