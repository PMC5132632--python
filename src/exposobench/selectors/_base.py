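"""Common selector machinery: result container and estimator base class."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from ..errors import ValidationError


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one variable-selection method on one dataset.

    ``selected`` is the set B of hits (0-based column indices), ``coef`` a
    full-length estimate vector that is zero off the selected set, and
    ``diagnostics`` a method-specific map (p-values, inclusion
    probabilities, chosen tuning values, ...).
    """

    method: str
    selected: tuple[int, ...]
    coef: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        coef = np.asarray(self.coef, dtype=float)
        selected = tuple(sorted(int(i) for i in self.selected))
        if selected and (selected[0] < 0 or selected[-1] >= coef.shape[0]):
            raise ValidationError("selected indices outside [0, p)")
        support = set(int(i) for i in np.flatnonzero(coef))
        if not support <= set(selected):
            raise ValidationError("coef must be zero outside the selected set")
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "selected", selected)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


class BaseSelector(BaseEstimator):
    """scikit-learn style base class for the six selection methods.

    Subclasses implement ``_fit(X, y)`` and set ``selected_`` (sorted index
    tuple), ``coef_`` (length-p vector, zero off the selection),
    ``intercept_`` and ``diagnostics_``.
    """

    #: short method name used in results tables and the CLI registry
    method_name: str = "base"

    def fit(self, X, y):
        X = check_array(X, dtype=float, ensure_min_samples=4)
        y = column_or_1d(y, warn=False).astype(float)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y have different numbers of samples")
        self.n_features_in_ = X.shape[1]
        self._fit(X, y)
        return self

    def _fit(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_result(self) -> SelectionResult:
        check_is_fitted(self, "coef_")
        return SelectionResult(
            method=self.method_name,
            selected=self.selected_,
            coef=self.coef_,
            diagnostics=self.diagnostics_,
        )

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def _center(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    ym = float(y.mean())
    return X - xm, y - ym, xm, ym


def _standardize(X: np.ndarray):
    xm = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - xm) / sd_safe, xm, sd_safe
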