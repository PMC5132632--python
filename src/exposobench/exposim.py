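"""Synthetic exposome and outcome generation.

The generative model: rows of the exposure matrix X are i.i.d. draws from a
mean-centered multivariate normal with a prescribed correlation matrix (a
small number of columns may be dichotomized to emulate binary questionnaire
items); a continuous health outcome is

    y = X beta + e,    e ~ N(0, sigma^2 I),

where beta is nonzero on k randomly chosen "true predictors".  The residual
variance sigma^2 is calibrated so that the proportion of outcome variance
explained by the true predictors is r2_per_predictor * k (3% per predictor
by default), keeping the signal-to-noise ratio constant within a scenario.

Seven scenario sets vary one ingredient at a time: 1 = baseline; 2/3 =
true predictors constrained to be weakly (< 0.2) / strongly (> 0.5)
correlated; 4/5 = exposures drawn from the halved / doubled-and-capped
correlation matrix; 6 = exposures bootstrapped from a raw table instead of
Gaussian draws; 7 = effect sizes drawn from U[0.5, 1.5] instead of all 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .corrstruct import CorrelationMatrix, scale_correlations
from .errors import FeasibilityError, ValidationError

DEFAULT_N = 1200
DEFAULT_P = 237
DEFAULT_R2_PER_PREDICTOR = 0.03
DEFAULT_K_VALUES = (0, 1, 2, 3, 5, 10, 25)

#: default positive-response proportions for the dichotomized columns
DEFAULT_BINARY_PROPS = (0.1, 0.25, 0.5, 0.75, 0.9)

EFFECT_MODES = ("fixed_one", "uniform_0.5_1.5")
CONSTRAINTS = ("none", "all_pairwise_abs_below_0.2", "all_pairwise_abs_above_0.5")
SIGMA_VARIANTS = ("sigma", "sigma_minus", "sigma_plus")
EXPOSURE_MODES = ("gaussian", "bootstrap")


def default_binary_spec(p: int, props: Sequence[float] = DEFAULT_BINARY_PROPS):
    """Evenly spread binary columns with the default positive proportions."""
    m = len(props)
    idx = [round(i * p / m) for i in range(m)]
    return tuple(zip(idx, props))


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design (scenario set x k)."""

    set_id: int
    k: int
    n: int = DEFAULT_N
    p: int = DEFAULT_P
    effect_mode: str = "fixed_one"
    predictor_constraint: str = "none"
    sigma_variant: str = "sigma"
    exposure_mode: str = "gaussian"
    r2_per_predictor: float = DEFAULT_R2_PER_PREDICTOR
    binary_spec: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        if not 1 <= self.set_id <= 7:
            raise ValidationError(f"set_id must be 1..7, got {self.set_id}")
        if not 0 <= self.k <= self.p:
            raise ValidationError(f"k={self.k} outside [0, p={self.p}]")
        if self.k >= 1 and not 0 < self.r2_per_predictor * self.k < 1:
            raise ValidationError(
                f"r2_per_predictor*k = {self.r2_per_predictor * self.k} must lie in (0, 1)"
            )
        if self.effect_mode not in EFFECT_MODES:
            raise ValidationError(f"unknown effect_mode {self.effect_mode!r}")
        if self.predictor_constraint not in CONSTRAINTS:
            raise ValidationError(f"unknown predictor_constraint {self.predictor_constraint!r}")
        if self.sigma_variant not in SIGMA_VARIANTS:
            raise ValidationError(f"unknown sigma_variant {self.sigma_variant!r}")
        if self.exposure_mode not in EXPOSURE_MODES:
            raise ValidationError(f"unknown exposure_mode {self.exposure_mode!r}")
        for j, prop in self.binary_spec:
            if not 0 <= j < self.p:
                raise ValidationError(f"binary column index {j} outside [0, p)")
            if not 0.0 < prop < 1.0:
                raise ValidationError(f"binary proportion {prop} outside (0, 1)")


def scenario(set_id: int, k: int, **overrides) -> ScenarioSpec:
    """Build the ScenarioSpec for one scenario set with its defining tweaks."""
    tweaks: dict = {}
    if set_id == 2:
        tweaks["predictor_constraint"] = "all_pairwise_abs_below_0.2"
    elif set_id == 3:
        tweaks["predictor_constraint"] = "all_pairwise_abs_above_0.5"
    elif set_id == 4:
        tweaks["sigma_variant"] = "sigma_minus"
    elif set_id == 5:
        tweaks["sigma_variant"] = "sigma_plus"
    elif set_id == 6:
        tweaks["exposure_mode"] = "bootstrap"
    elif set_id == 7:
        tweaks["effect_mode"] = "uniform_0.5_1.5"
    tweaks.update(overrides)
    p = tweaks.pop("p", DEFAULT_P)
    if "binary_spec" not in tweaks:
        tweaks["binary_spec"] = default_binary_spec(p)
    return ScenarioSpec(set_id=set_id, k=k, p=p, **tweaks)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated run: exposures X, outcome y, and the generating truth."""

    X: np.ndarray
    y: np.ndarray
    true_idx: tuple[int, ...]
    beta: np.ndarray
    sigma2: float
    seed: int

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],) or beta.shape != (X.shape[1],):
            raise ValidationError("inconsistent X/y/beta dimensions")
        true_idx = tuple(sorted(int(i) for i in self.true_idx))
        support = tuple(int(i) for i in np.flatnonzero(beta))
        if support != true_idx:
            raise ValidationError("beta must be nonzero exactly on true_idx")
        if len(true_idx) >= 1 and not self.sigma2 > 0:
            raise ValidationError("sigma2 must be positive when k >= 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "true_idx", true_idx)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return len(self.true_idx)

    def to_dir(self, path: str | Path) -> None:
        """Write X.csv / y.csv / truth.csv for external method harnesses."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cols = [f"X{j + 1:03d}" for j in range(self.p)]
        pd.DataFrame(self.X, columns=cols).to_csv(path / "X.csv", index=False)
        pd.DataFrame({"y": self.y}).to_csv(path / "y.csv", index=False)
        pd.DataFrame(
            {"variable": cols, "beta": self.beta, "is_true": np.isin(np.arange(self.p), self.true_idx).astype(int)}
        ).to_csv(path / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# component operations

_FACTOR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _mvn_factor(sigma: CorrelationMatrix) -> np.ndarray:
    """Square-root factor of sigma (eigenvalue form, robust to eigenvalues ~0)."""
    key = id(sigma.values)
    hit = _FACTOR_CACHE.get(key)
    if hit is not None and hit[0] is sigma.values:
        return hit[1]
    lam, Q = np.linalg.eigh(sigma.values)
    factor = Q * np.sqrt(np.clip(lam, 0.0, None))
    if len(_FACTOR_CACHE) > 16:
        _FACTOR_CACHE.clear()
    _FACTOR_CACHE[key] = (sigma.values, factor)
    return factor


def draw_exposome(
    sigma: CorrelationMatrix,
    n: int,
    binary_spec: Sequence[tuple[int, float]] = (),
    seed: int = 0,
) -> np.ndarray:
    """Draw n i.i.d. mean-centered multivariate-normal exposure rows.

    Columns listed in ``binary_spec`` are replaced by 0/1 indicators of the
    latent Gaussian exceeding the quantile that gives the requested positive
    proportion.
    """
    if n < 2:
        raise ValidationError("need n >= 2 exposure rows")
    rng = substream(seed, "exposome")
    Z = rng.standard_normal((n, sigma.p))
    X = Z @ _mvn_factor(sigma).T
    for j, prop in binary_spec:
        thr = stats.norm.ppf(1.0 - prop)
        X[:, j] = (X[:, j] > thr).astype(float)
    return X


def select_true_predictors(
    sigma: CorrelationMatrix,
    k: int,
    constraint: str = "none",
    seed: int = 0,
    max_draws: int = 10**6,
) -> tuple[int, ...]:
    """Draw k distinct true-predictor indices satisfying a pairwise constraint.

    The constraint (< 0.2 or > 0.5 absolute pairwise correlation among all
    true predictors) is checked on ``sigma`` itself, not on sample
    correlations.  Subsets are drawn by rejection sampling, approximating a
    uniform draw over qualifying subsets.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        return ()
    if constraint == "none":
        rng = substream(seed, "predictors")
        return tuple(sorted(int(i) for i in rng.choice(sigma.p, size=k, replace=False)))

    if constraint == "all_pairwise_abs_below_0.2":
        ok = np.abs(sigma.values) < 0.2
    elif constraint == "all_pairwise_abs_above_0.5":
        ok = np.abs(sigma.values) > 0.5
    else:
        raise ValidationError(f"unknown constraint {constraint!r}")
    np.fill_diagonal(ok, True)

    rng = substream(seed, "predictors")
    draws = 0
    while draws < max_draws:
        # whole-subset rejection first; fall back to sequential growth
        idx = rng.choice(sigma.p, size=k, replace=False)
        draws += 1
        if np.all(ok[np.ix_(idx, idx)]):
            return tuple(sorted(int(i) for i in idx))
        if draws % 200 == 0:
            chosen = [int(rng.integers(sigma.p))]
            for _ in range(k - 1):
                cand = np.flatnonzero(np.all(ok[:, chosen], axis=1))
                cand = cand[~np.isin(cand, chosen)]
                if cand.size == 0:
                    break
                chosen.append(int(rng.choice(cand)))
            draws += k
            if len(chosen) == k:
                return tuple(sorted(chosen))
    raise FeasibilityError(
        f"no {k}-subset satisfying {constraint!r} found within {max_draws} draws"
    )


def draw_effect_sizes(k: int, effect_mode: str = "fixed_one", seed: int = 0) -> np.ndarray:
    """Effect sizes for the k true predictors (all 1, or i.i.d. U[0.5, 1.5])."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    if effect_mode == "fixed_one":
        return np.ones(k)
    if effect_mode == "uniform_0.5_1.5":
        return substream(seed, "effects").uniform(0.5, 1.5, size=k)
    raise ValidationError(f"unknown effect_mode {effect_mode!r}")


def residual_variance(
    sigma: CorrelationMatrix,
    beta: np.ndarray,
    k: int,
    r2_per_predictor: float = DEFAULT_R2_PER_PREDICTOR,
) -> float:
    """Residual variance giving the true predictors R^2 = r2_per_predictor * k.

    With signal variance v = beta' Sigma beta (on the latent Gaussian scale),
    returns sigma^2 = v (1 - R^2) / R^2.  For k = 0 the constraint
    degenerates and sigma^2 = 1 by convention.
    """
    if k == 0:
        return 1.0
    r2 = r2_per_predictor * k
    if not 0.0 < r2 < 1.0:
        raise ValidationError(f"total R^2 = {r2} must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    v = float(beta @ sigma.values @ beta)
    return v * (1.0 - r2) / r2


def generate_outcome(X: np.ndarray, beta: np.ndarray, sigma2: float, seed: int = 0) -> np.ndarray:
    """y = X beta + e with e i.i.d. N(0, sigma^2)."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    if X.shape[1] != beta.shape[0]:
        raise ValidationError("X and beta dimensions disagree")
    e = substream(seed, "outcome").normal(0.0, np.sqrt(sigma2), size=X.shape[0])
    return X @ beta + e


def bootstrap_exposome(raw_table, n: int, seed: int = 0) -> np.ndarray:
    """Resample n exposure rows with replacement from a raw table.

    Emulates departure from Gaussianity (skewness, outliers).  Columns are
    mean-centered after resampling.
    """
    if raw_table is None:
        raise ValidationError(
            "bootstrap exposure mode needs a raw exposure table; "
            "use gaussian mode if none is available"
        )
    raw = np.asarray(raw_table, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValidationError("raw exposure table must be a non-empty 2-D array")
    rng = substream(seed, "bootstrap")
    rows = rng.integers(0, raw.shape[0], size=n)
    X = raw[rows].copy()
    return X - X.mean(axis=0)


_VARIANT_CACHE: dict[tuple[int, str], tuple[np.ndarray, CorrelationMatrix]] = {}


def variant_sigma(sigma: CorrelationMatrix, variant: str) -> CorrelationMatrix:
    """The baseline, halved (sigma_minus) or doubled-and-capped (sigma_plus) matrix."""
    if variant == "sigma":
        return sigma
    key = (id(sigma.values), variant)
    hit = _VARIANT_CACHE.get(key)
    if hit is not None and hit[0] is sigma.values:
        return hit[1]
    if variant == "sigma_minus":
        out = scale_correlations(sigma, 0.5)
    elif variant == "sigma_plus":
        out = scale_correlations(sigma, 2.0)
    else:
        raise ValidationError(f"unknown sigma variant {variant!r}")
    if len(_VARIANT_CACHE) > 16:
        _VARIANT_CACHE.clear()
    _VARIANT_CACHE[key] = (sigma.values, out)
    return out


def simulate_run(
    spec: ScenarioSpec,
    sigma: CorrelationMatrix,
    seed: int = 0,
    raw_table=None,
) -> SimulatedDataset:
    """Simulate one dataset: predictors -> effects -> sigma^2 -> exposome -> outcome.

    Fully reproducible from (spec, seed).  ``sigma`` is the baseline
    correlation matrix; the spec's sigma_variant is applied here.  Bootstrap
    exposure mode additionally needs ``raw_table``.
    """
    if sigma.p != spec.p:
        raise ValidationError(f"sigma is {sigma.p}x{sigma.p} but spec.p = {spec.p}")
    sig = variant_sigma(sigma, spec.sigma_variant)
    true_idx = select_true_predictors(
        sig, spec.k, spec.predictor_constraint, seed=seed
    )
    effects = draw_effect_sizes(spec.k, spec.effect_mode, seed=seed)
    beta = np.zeros(spec.p)
    beta[list(true_idx)] = effects
    sigma2 = residual_variance(sig, beta, spec.k, spec.r2_per_predictor)
    if spec.exposure_mode == "bootstrap":
        X = bootstrap_exposome(raw_table, spec.n, seed=seed)
    else:
        X = draw_exposome(sig, spec.n, spec.binary_spec, seed=seed)
    y = generate_outcome(X, beta, sigma2, seed=seed)
    return SimulatedDataset(X=X, y=y, true_idx=true_idx, beta=beta, sigma2=sigma2, seed=seed)
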