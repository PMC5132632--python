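"""The six variable-selection methods, as scikit-learn style estimators.

Each selector implements ``fit(X, y)`` and exposes ``selected_`` (the hit
set B), ``coef_`` (full-length coefficient vector, zero off the selection)
and ``diagnostics_``; ``to_result()`` packages these into a
:class:`SelectionResult`.  Module-level functions (:func:`ewas`,
:func:`elastic_net`, ...) are thin wrappers for one-shot use, and a registry
maps method names to estimator factories so external selectors can be
plugged into the benchmark.
"""

from __future__ import annotations

from ._base import BaseSelector, SelectionResult
from ._dsa import DSASelector
from ._enet import ElasticNetSelector
from ._ess import ESSConfig, ESSSelector, mppi_null_threshold
from ._ewas import EWASMLRSelector, EWASSelector
from ._ridge import ridge_refit
from ._spls import SPLSSelector

__all__ = [
    "BaseSelector", "SelectionResult",
    "EWASSelector", "EWASMLRSelector", "ElasticNetSelector", "SPLSSelector",
    "ESSSelector", "ESSConfig", "DSASelector",
    "ewas", "ewas_mlr", "elastic_net", "spls", "ess_select", "dsa",
    "ridge_refit", "mppi_null_threshold",
    "SELECTOR_REGISTRY", "register_selector", "make_selector",
]

SELECTOR_REGISTRY: dict[str, type[BaseSelector]] = {}


def register_selector(cls: type[BaseSelector]) -> type[BaseSelector]:
    """Register an estimator class under its ``method_name``."""
    SELECTOR_REGISTRY[cls.method_name] = cls
    return cls


for _cls in (EWASSelector, EWASMLRSelector, ElasticNetSelector, SPLSSelector,
             ESSSelector, DSASelector):
    register_selector(_cls)


def make_selector(name: str, **params) -> BaseSelector:
    """Instantiate a registered selector by method name."""
    try:
        cls = SELECTOR_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown selector {name!r}; registered: {sorted(SELECTOR_REGISTRY)}"
        ) from None
    return cls(**params)


def _run(est: BaseSelector, X, y) -> SelectionResult:
    return est.fit(X, y).to_result()


def ewas(X, y, correction: str = "bh", level: float = 0.05, **kw) -> SelectionResult:
    """Univariate screening with multiplicity correction."""
    return _run(EWASSelector(correction=correction, level=level, **kw), X, y)


def ewas_mlr(X, y, correction: str = "bh", level: float = 0.05, **kw) -> SelectionResult:
    """EWAS followed by a multiple-regression confirmation stage."""
    return _run(EWASMLRSelector(correction=correction, level=level, **kw), X, y)


def elastic_net(X, y, folds: int = 10, seed: int = 0, **kw) -> SelectionResult:
    """Elastic net with the cross-validated one-standard-error rule."""
    return _run(ElasticNetSelector(n_folds=folds, random_state=seed, **kw), X, y)


def spls(X, y, folds: int = 5, K_grid=None, eta_grid=None, seed: int = 0, **kw) -> SelectionResult:
    """Sparse PLS with CV-calibrated component count and threshold."""
    if K_grid is not None:
        kw["K_grid"] = K_grid
    if eta_grid is not None:
        kw["eta_grid"] = eta_grid
    return _run(SPLSSelector(n_folds=folds, random_state=seed, **kw), X, y)


def ess_select(X, y, config: ESSConfig | None = None, mppi_threshold: float = 0.9,
               seed: int = 0) -> SelectionResult:
    """Evolutionary stochastic search with an MPPI selection threshold."""
    config = config or ESSConfig()
    est = ESSSelector(
        n_iter=config.n_iter, burn_in=config.burn_in, n_chains=config.n_chains,
        prior_model_size=config.prior_model_size,
        prior_size_variance=config.prior_size_variance,
        posterior_model_threshold=config.posterior_model_threshold,
        temperature_ratio=config.temperature_ratio, g=config.g,
        max_model_size=config.max_model_size,
        mppi_threshold=mppi_threshold, random_state=seed,
    )
    return _run(est, X, y)


def dsa(X, y, max_size: int = 40, folds: int = 5, seed: int = 0) -> SelectionResult:
    """Deletion/substitution/addition search with CV-chosen size."""
    return _run(DSASelector(max_size=max_size, n_folds=folds, random_state=seed), X, y)
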