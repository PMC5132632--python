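"""Evolutionary stochastic search: Bayesian variable selection.

Gaussian linear regression with a Zellner g-prior (g = n) on coefficients
and a beta-binomial prior on model size with prescribed mean E and variance
rho.  The 2^p model space is sampled by an evolutionary Monte Carlo scheme:
several chains run at a geometric temperature ladder and exchange
information through genetic moves (per-chain mutation = add/remove/swap a
variable, uniform crossover between chains, and state exchange between
neighboring temperatures).

After burn-in, posterior model probabilities are estimated from the visit
frequencies of the untempered (cold) chain; models above a posterior
threshold are retained and the marginal posterior probability of inclusion
(MPPI) of each covariate is computed over the retained models.  A covariate
is selected when its MPPI exceeds a threshold, by default calibrated as a
high quantile of the MPPI distribution under the global null (no covariate
associated with the outcome).  Coefficients for the selected set come from
a ridge refit (:func:`ridge_refit`).

The study's prior settings: E = 3, rho = 3 for scenarios with fewer than 5
true predictors, E = k + 2, rho = 5 otherwise; 20,000 iterations with 5,000
burn-in and 3 chains.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import betaln

from .._rng import child_seed, substream
from ..errors import ValidationError
from ._base import BaseSelector
from ._ridge import ridge_refit


@dataclass(frozen=True)
class ESSConfig:
    """Sampler settings for the evolutionary stochastic search."""

    n_iter: int = 20000
    burn_in: int = 5000
    n_chains: int = 3
    prior_model_size: float = 3.0      # E, a-priori expected model size
    prior_size_variance: float = 3.0   # rho, its a-priori variance
    posterior_model_threshold: float = 0.01
    mppi_quantile: float | None = None  # default 1 - 0.05/p
    temperature_ratio: float = 1.3
    g: float | None = None             # default n
    max_model_size: int | None = None

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValidationError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValidationError("need at least one chain")
        if not 0.0 < self.posterior_model_threshold < 1.0:
            raise ValidationError("posterior_model_threshold must lie in (0, 1)")
        if self.mppi_quantile is not None and not 0.0 < self.mppi_quantile < 1.0:
            raise ValidationError("mppi_quantile must lie in (0, 1)")

    @classmethod
    def for_k(cls, k: int, **overrides) -> "ESSConfig":
        """Prior settings keyed to the scenario's number of true predictors."""
        if k < 5:
            base = cls(prior_model_size=3.0, prior_size_variance=3.0)
        else:
            base = cls(prior_model_size=float(k + 2), prior_size_variance=5.0)
        return replace(base, **overrides) if overrides else base


def _size_prior_logpmf(p: int, E: float, rho: float) -> np.ndarray:
    """log prior of each model size 0..p for mean E and variance rho.

    A binomial prior cannot be over-dispersed (its variance tops out at
    E(1 - E/p)); when rho exceeds that, a beta-binomial with matching mean
    and variance is substituted.  The returned array excludes the
    uniform-over-subsets factor: the model prior is size prior / C(p, q).
    """
    if not 0 < E < p:
        raise ValidationError("prior model size must lie in (0, p)")
    m = E / p
    base_var = p * m * (1 - m)
    q = np.arange(p + 1)
    lchoose = (
        math.lgamma(p + 1)
        - np.array([math.lgamma(i + 1) + math.lgamma(p - i + 1) for i in q])
    )
    if rho < base_var:
        # under-dispersed target: independent-inclusion binomial at mean E
        logpmf = lchoose + q * math.log(m) + (p - q) * math.log1p(-m)
    else:
        c = max(rho / base_var, 1.0 + 1e-9)
        s = (p - c) / (c - 1.0)  # a + b
        a, b = s * m, s * (1 - m)
        logpmf = lchoose + betaln(q + a, p - q + b) - betaln(a, b)
    return logpmf - lchoose  # per-model prior: pmf divided by C(p, q)


class _ModelScore:
    """Cached g-prior log marginal (+ size prior) over models (index tuples)."""

    def __init__(self, X, y, g, size_logprior):
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0, ddof=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
        self.G = Xc.T @ Xc
        yc = y - y.mean()
        self.c = Xc.T @ yc
        self.yty = float(yc @ yc)
        self.n = X.shape[0]
        self.g = float(g)
        self.size_logprior = size_logprior
        self._cache: dict[tuple, float] = {}

    def r_squared(self, model: tuple) -> float:
        if not model or self.yty <= 0:
            return 0.0
        S = list(model)
        Gss = self.G[np.ix_(S, S)]
        try:
            chol = cho_factor(Gss + 1e-10 * np.eye(len(S)), lower=True)
            fit = float(self.c[S] @ cho_solve(chol, self.c[S]))
        except np.linalg.LinAlgError:
            return 0.0
        return min(max(fit / self.yty, 0.0), 1.0 - 1e-12)

    def log_post(self, model: tuple) -> float:
        lp = self._cache.get(model)
        if lp is not None:
            return lp
        q = len(model)
        n, g = self.n, self.g
        r2 = self.r_squared(model)
        log_bf = 0.5 * ((n - 1 - q) * math.log1p(g) - (n - 1) * math.log1p(g * (1.0 - r2)))
        lp = log_bf + float(self.size_logprior[q])
        if len(self._cache) > 200_000:
            self._cache.clear()
        self._cache[model] = lp
        return lp


def _propose_mutation(model: tuple, p: int, qmax: int, rng) -> tuple[tuple, float] | None:
    """Add/remove/swap proposal with its log Hastings ratio."""
    q = len(model)
    can_add = q < qmax
    can_remove = q > 0
    u = rng.random()
    in_model = set(model)
    if can_add and (not can_remove or u < 0.45):
        j = int(rng.integers(p))
        while j in in_model:
            j = int(rng.integers(p))
        new = tuple(sorted(model + (j,)))
        # forward: add uniform among p-q absent; reverse: remove among q+1
        log_q = math.log(p - q) - math.log(q + 1)
        return new, log_q
    if can_remove and (not can_add or u < 0.9):
        j = model[int(rng.integers(q))]
        new = tuple(v for v in model if v != j)
        log_q = math.log(q) - math.log(p - q + 1)
        return new, log_q
    if can_remove and can_add:
        out = model[int(rng.integers(q))]
        j = int(rng.integers(p))
        while j in in_model:
            j = int(rng.integers(p))
        new = tuple(sorted(v for v in model if v != out) + [j])
        return tuple(sorted(new)), 0.0  # symmetric
    return None


def _run_sampler(score: _ModelScore, p: int, config: ESSConfig, rng):
    """Evolutionary MC over model space; returns cold-chain visit counts."""
    n_chains = config.n_chains
    betas = [config.temperature_ratio ** (-l) for l in range(n_chains)]
    qmax = config.max_model_size or min(p, score.n - 2, 80)
    states: list[tuple] = [() for _ in range(n_chains)]
    lps = [score.log_post(s) for s in states]
    visits: Counter = Counter()
    for it in range(config.n_iter):
        u = rng.random()
        if u < 0.7 or n_chains == 1:
            for l in range(n_chains):
                prop = _propose_mutation(states[l], p, qmax, rng)
                if prop is None:
                    continue
                new, log_q = prop
                lp_new = score.log_post(new)
                if math.log(rng.random() + 1e-300) < betas[l] * (lp_new - lps[l]) + log_q:
                    states[l], lps[l] = new, lp_new
        elif u < 0.85 and n_chains >= 2:
            i, j = rng.choice(n_chains, size=2, replace=False)
            si, sj = set(states[i]), set(states[j])
            c1, c2 = set(si & sj), set(si & sj)
            for v in si ^ sj:
                (c1 if rng.random() < 0.5 else c2).add(v)
            c1 = tuple(sorted(c1))
            c2 = tuple(sorted(c2))
            if len(c1) <= qmax and len(c2) <= qmax:
                lp1, lp2 = score.log_post(c1), score.log_post(c2)
                delta = betas[i] * (lp1 - lps[i]) + betas[j] * (lp2 - lps[j])
                if math.log(rng.random() + 1e-300) < delta:
                    states[i], lps[i] = c1, lp1
                    states[j], lps[j] = c2, lp2
        elif n_chains >= 2:
            l = int(rng.integers(n_chains - 1))
            delta = (betas[l] - betas[l + 1]) * (lps[l + 1] - lps[l])
            if math.log(rng.random() + 1e-300) < delta:
                states[l], states[l + 1] = states[l + 1], states[l]
                lps[l], lps[l + 1] = lps[l + 1], lps[l]
        if it >= config.burn_in:
            visits[states[0]] += 1
    return visits


def _mppi_from_visits(visits: Counter, p: int, threshold: float) -> tuple[np.ndarray, dict]:
    total = sum(visits.values())
    freqs = {m: v / total for m, v in visits.items()}
    retained = {m: f for m, f in freqs.items() if f > threshold}
    mppi = np.zeros(p)
    if retained:
        mass = sum(retained.values())
        for m, f in retained.items():
            for j in m:
                mppi[j] += f
        mppi /= mass
    return mppi, retained


class ESSSelector(BaseSelector):
    """Evolutionary stochastic search selector.

    Parameters mirror :class:`ESSConfig` (flattened for the scikit-learn
    parameter API) plus the MPPI selection threshold.  ``mppi_threshold``
    should normally come from :func:`mppi_null_threshold`; the default 0.9
    is a conservative stand-in when no null calibration is available.
    """

    method_name = "GUESS"

    def __init__(self, n_iter=20000, burn_in=5000, n_chains=3,
                 prior_model_size=3.0, prior_size_variance=3.0,
                 posterior_model_threshold=0.01, mppi_threshold=0.9,
                 temperature_ratio=1.3, g=None, max_model_size=None,
                 random_state=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.prior_model_size = prior_model_size
        self.prior_size_variance = prior_size_variance
        self.posterior_model_threshold = posterior_model_threshold
        self.mppi_threshold = mppi_threshold
        self.temperature_ratio = temperature_ratio
        self.g = g
        self.max_model_size = max_model_size
        self.random_state = random_state

    def _config(self) -> ESSConfig:
        return ESSConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, n_chains=self.n_chains,
            prior_model_size=self.prior_model_size,
            prior_size_variance=self.prior_size_variance,
            posterior_model_threshold=self.posterior_model_threshold,
            temperature_ratio=self.temperature_ratio, g=self.g,
            max_model_size=self.max_model_size,
        )

    def _fit(self, X, y):
        if not 0.0 <= self.mppi_threshold <= 1.0:
            raise ValidationError("mppi_threshold must lie in [0, 1]")
        config = self._config()
        n, p = X.shape
        g = config.g if config.g is not None else float(n)
        size_logprior = _size_prior_logpmf(p, config.prior_model_size,
                                           config.prior_size_variance)
        score = _ModelScore(X, y, g, size_logprior)
        rng = substream(self.random_state, "ess")
        visits = _run_sampler(score, p, config, rng)
        mppi, retained = _mppi_from_visits(visits, p, config.posterior_model_threshold)
        self.mppi_ = mppi
        selected = tuple(int(j) for j in np.flatnonzero(mppi > self.mppi_threshold))
        self.selected_ = selected
        self.coef_ = ridge_refit(X, y, selected)
        self.intercept_ = float(y.mean() - X.mean(axis=0) @ self.coef_)
        self.diagnostics_ = {
            "mppi": mppi,
            "retained_models": {m: f for m, f in sorted(
                retained.items(), key=lambda t: -t[1])},
            "mppi_threshold": float(self.mppi_threshold),
            "n_models_visited": len(visits),
        }


def mppi_null_threshold(
    sigma,
    n: int,
    config: ESSConfig | None = None,
    n_null_runs: int = 20,
    seed: int = 0,
    quantile: float | None = None,
) -> float:
    """MPPI selection threshold calibrated under the global null.

    Runs the sampler on ``n_null_runs`` datasets where no covariate is
    associated with the outcome, pools all per-variable MPPIs, and returns
    their ``1 - 0.05/p`` empirical quantile (or ``config.mppi_quantile`` /
    ``quantile`` when given).
    """
    from ..exposim import draw_exposome  # local import to avoid a cycle

    if n_null_runs < 1:
        raise ValidationError("n_null_runs must be >= 1")
    config = config or ESSConfig()
    p = sigma.p
    level = quantile or config.mppi_quantile or (1.0 - 0.05 / p)
    pooled = []
    for r in range(n_null_runs):
        X = draw_exposome(sigma, n, seed=child_seed(seed, "ess-null-x", r))
        y = substream(seed, "ess-null-y", r).standard_normal(n)
        est = ESSSelector(
            n_iter=config.n_iter, burn_in=config.burn_in, n_chains=config.n_chains,
            prior_model_size=config.prior_model_size,
            prior_size_variance=config.prior_size_variance,
            posterior_model_threshold=config.posterior_model_threshold,
            temperature_ratio=config.temperature_ratio, g=config.g,
            max_model_size=config.max_model_size,
            mppi_threshold=1.0,  # selection itself is irrelevant here
            random_state=child_seed(seed, "ess-null-run", r),
        ).fit(X, y)
        pooled.append(est.mppi_)
    # the level sits deep in the pooled tail; the upper empirical quantile
    # ("higher" interpolation) is the conservative estimate
    return float(np.quantile(np.concatenate(pooled), level, method="higher"))
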