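"""Performance statistics for variable selection against a known truth.

Classical criteria (sensitivity, specificity, false discovery proportion),
coefficient accuracy (mean absolute bias over all / true / unrelated
covariates), and correlation-aware alternatives:

    AltSens = (1/k)   sum_{a in A} max_{b in B} |corr(a, b)|
    AltFDP  = 1 - (1/n_B) sum_{b in B} max_{a in A} |corr(b, a)|

where A is the true-predictor set and B the selected set.  These credit a
method that misses a true predictor but selects a strongly correlated proxy:
AltSens >= sensitivity and AltFDP <= FDP always.  Conventions: an empty
selection has FDP 0 (nothing was mistakenly selected) and, by extension,
AltSens = AltFDP = 0; sensitivity, FDP and the alternative metrics are NaN
(not computed) when there are no true predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import ValidationError
from .exposim import SimulatedDataset
from .selectors import SelectionResult

NA = float("nan")


@dataclass(frozen=True)
class PerformanceRecord:
    """The performance statistics for one (method, run) pair."""

    sensitivity: float
    specificity: float
    fdp: float
    alt_sens: float
    alt_fdp: float
    n_b_over_k: float
    mab_all: float
    mab_true: float
    mab_null: float

    def __post_init__(self):
        for f in ("sensitivity", "specificity", "fdp", "alt_sens", "alt_fdp"):
            v = getattr(self, f)
            if not math.isnan(v) and not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{f} = {v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_sets(A, B, p: int) -> tuple[np.ndarray, np.ndarray]:
    A = np.unique(np.asarray(list(A), dtype=int)) if len(A) else np.empty(0, dtype=int)
    B = np.unique(np.asarray(list(B), dtype=int)) if len(B) else np.empty(0, dtype=int)
    for name, S in (("A", A), ("B", B)):
        if S.size and (S.min() < 0 or S.max() >= p):
            raise ValidationError(f"{name} contains indices outside [0, p)")
    return A, B


def classification_metrics(A, B, p: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, FDP) of selected set B against truth A.

    sensitivity = |A & B| / |A| (NaN if A is empty); specificity is the
    proportion of non-true covariates not selected; FDP = |B \\ A| / |B|,
    defined as 0 when B is empty.
    """
    A, B = _check_sets(A, B, p)
    inter = np.intersect1d(A, B, assume_unique=True).size
    sens = inter / A.size if A.size else NA
    n_neg = p - A.size
    spec = (n_neg - (B.size - inter)) / n_neg if n_neg else NA
    fdp = (B.size - inter) / B.size if B.size else 0.0
    return sens, spec, fdp


def mean_absolute_bias(beta_true, beta_hat, subset: str = "all") -> float:
    """Mean |beta_hat - beta_true| over all / true / null (unrelated) covariates.

    Unselected covariates carry a zero estimate, so they contribute |beta_i|
    when truly active and 0 otherwise.  Returns NaN for an empty subset.
    """
    beta_true = np.asarray(beta_true, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_true.shape != beta_hat.shape:
        raise ValidationError("beta_true and beta_hat must have equal length")
    err = np.abs(beta_hat - beta_true)
    if subset == "all":
        mask = np.ones_like(err, dtype=bool)
    elif subset == "true":
        mask = beta_true != 0
    elif subset == "null":
        mask = beta_true == 0
    else:
        raise ValidationError(f"unknown subset {subset!r}")
    if not mask.any():
        return NA
    return float(err[mask].mean())


def alt_metrics(A, B, corr: np.ndarray) -> tuple[float, float]:
    """Correlation-aware (AltSens, AltFDP); both 0 when B is empty, NaN when A is."""
    p = corr.shape[0]
    A, B = _check_sets(A, B, p)
    if not A.size:
        return NA, NA
    if not B.size:
        return 0.0, 0.0
    sub = np.abs(np.asarray(corr, dtype=float)[np.ix_(A, B)])
    alt_sens = float(sub.max(axis=1).mean())
    alt_fdp = 1.0 - float(sub.max(axis=0).mean())
    return alt_sens, alt_fdp


def extended_selection(B, corr: np.ndarray, alpha: float) -> tuple[int, ...]:
    """Augment B with every covariate correlated above alpha with some hit.

    The extended protocol treats strong correlates of the hits as selected
    too; classical metrics can then be recomputed on the augmented set.
    Monotone in alpha: a lower threshold augments with at least as much.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    _, B = _check_sets((), B, p)
    if not B.size:
        return ()
    masked = np.abs(corr[:, B]).max(axis=1)
    masked[B] = np.inf  # hits stay in regardless of self-correlation handling
    out = np.flatnonzero(masked > alpha)
    return tuple(int(j) for j in np.union1d(out, B))


def score_run(
    dataset: SimulatedDataset,
    result: SelectionResult,
    corr_source: str = "empirical",
    sigma: np.ndarray | None = None,
) -> PerformanceRecord:
    """Assemble the full PerformanceRecord for one method on one run.

    Alt metrics use the sample correlation matrix of the run's X by default
    (``corr_source="empirical"``); pass ``corr_source="sigma"`` with the
    generating matrix for the population-correlation variant.
    """
    p = dataset.p
    if result.coef.shape != (p,):
        raise ValidationError("result.coef length differs from dataset p")
    A, B = dataset.true_idx, result.selected
    sens, spec, fdp = classification_metrics(A, B, p)
    if len(A):
        if corr_source == "empirical":
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.corrcoef(dataset.X, rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)
        elif corr_source == "sigma":
            if sigma is None:
                raise ValidationError("corr_source='sigma' needs the sigma argument")
            corr = np.asarray(sigma, dtype=float)
        else:
            raise ValidationError(f"unknown corr_source {corr_source!r}")
        alt_sens, alt_fdp = alt_metrics(A, B, corr)
        n_b_over_k = len(B) / len(A)
    else:
        alt_sens = alt_fdp = n_b_over_k = NA
        fdp = NA  # not computed for k = 0 scenarios
        sens = NA
    return PerformanceRecord(
        sensitivity=sens,
        specificity=spec,
        fdp=fdp,
        alt_sens=alt_sens,
        alt_fdp=alt_fdp,
        n_b_over_k=n_b_over_k,
        mab_all=mean_absolute_bias(dataset.beta, result.coef, "all"),
        mab_true=mean_absolute_bias(dataset.beta, result.coef, "true"),
        mab_null=mean_absolute_bias(dataset.beta, result.coef, "null"),
    )
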