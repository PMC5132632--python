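"""Ridge refit of a selected variable subset.

The evolutionary stochastic search selector reports coefficients from a
ridge regression on its selected columns (a conservative estimation step:
direct posterior coefficient simulation over all visited models would be
prohibitive).  The penalty is chosen by generalized cross-validation (GCV)
on the selected submatrix; the intercept is unpenalized (handled by
centering).
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError


def _gcv_ridge(Z: np.ndarray, yc: np.ndarray, penalties: np.ndarray):
    """GCV score for each penalty via SVD of the centered design."""
    n = Z.shape[0]
    U, d, Vt = np.linalg.svd(Z, full_matrices=False)
    uy = U.T @ yc
    yy = float(yc @ yc)
    scores = np.empty(len(penalties))
    for i, lam in enumerate(penalties):
        shrink = d**2 / (d**2 + lam)
        rss = yy - 2 * np.sum(shrink * uy**2) + np.sum(shrink**2 * uy**2)
        df = float(np.sum(shrink)) + 1.0  # +1 for the intercept
        scores[i] = n * rss / (n - df) ** 2 if n > df else np.inf
    return scores, (U, d, Vt, uy)


def ridge_refit(
    X: np.ndarray,
    y: np.ndarray,
    selected,
    penalty: float | None = None,
) -> np.ndarray:
    """Ridge coefficients for the selected columns, zeros elsewhere.

    Parameters
    ----------
    X, y
        Full design and outcome.
    selected
        Column indices to refit on (empty -> all-zero vector).
    penalty
        Ridge penalty on the centered design; ``None`` chooses it by GCV
        over a log-spaced grid.

    Returns
    -------
    Length-p coefficient vector on the original covariate scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    sel = np.unique(np.asarray(list(selected), dtype=int)) if len(selected) else np.empty(0, int)
    out = np.zeros(p)
    if sel.size == 0:
        return out
    if sel.min() < 0 or sel.max() >= p:
        raise ValidationError("selected indices outside [0, p)")
    Z = X[:, sel]
    Z = Z - Z.mean(axis=0)
    yc = y - y.mean()
    if penalty is None:
        grid = np.logspace(-6, 4, 41)
        scores, (U, d, Vt, uy) = _gcv_ridge(Z, yc, grid)
        lam = float(grid[int(np.argmin(scores))])
    else:
        lam = float(penalty)
        U, d, Vt = np.linalg.svd(Z, full_matrices=False)
        uy = U.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = Vt.T @ (d * uy / (d**2 + lam))
    if lam == 0:
        coef = np.nan_to_num(coef, nan=0.0, posinf=0.0, neginf=0.0)
    out[sel] = coef
    return out
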