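"""Benchmark orchestration: scenario sets x k x runs x methods.

One simulated dataset per (scenario set, k, run) is shared by every
configured method; each method's selection is scored against the generating
truth and the stream of per-run records is aggregated into study-style
summary tables (per-scenario means, then mean [min; max] of the
per-scenario means across scenarios).

Runs are independent work units with seeds bound to their (set, k, run)
key, so results are identical regardless of execution order or worker
count, and an interrupted experiment resumes by skipping records already
persisted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from ._rng import child_seed
from .corrstruct import CorrelationMatrix, read_matrix, surrogate_sigma
from .errors import ValidationError
from .exposim import DEFAULT_K_VALUES, SimulatedDataset, scenario, simulate_run
from .perfmetrics import PerformanceRecord, score_run
from .selectors import ESSConfig, make_selector, mppi_null_threshold

log = logging.getLogger("exposobench")

STAT_COLUMNS = (
    "sensitivity", "alt_sens", "fdp", "alt_fdp", "specificity",
    "n_b_over_k", "mab_all", "mab_true", "mab_null", "n_selected",
)

DEFAULT_METHODS: dict[str, dict] = {
    "EWAS": {}, "EWAS-MLR": {}, "ENET": {}, "sPLS": {}, "GUESS": {}, "DSA": {},
}


@dataclass
class ExperimentConfig:
    """Full description of one benchmark experiment."""

    scenario_sets: tuple[int, ...] = (1,)
    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    n_runs: int = 100
    methods: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_METHODS))
    sigma_path: str | None = None          # CSV/XLSX; None -> surrogate
    surrogate_p: int = 237
    surrogate_target: tuple[float, float] = (0.83, 0.78)
    n: int = 1200
    seed: int = 0
    output_dir: str | None = None
    n_jobs: int = 1
    raw_exposures_path: str | None = None  # for bootstrap scenario set 6
    ess_null_runs: int = 20                # null runs for MPPI calibration
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if not self.methods:
            raise ValidationError("configure at least one method")
        self.scenario_sets = tuple(int(s) for s in self.scenario_sets)
        self.k_values = tuple(int(k) for k in self.k_values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scenario_sets"] = list(self.scenario_sets)
        data["k_values"] = list(self.k_values)
        data["surrogate_target"] = list(self.surrogate_target)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_sigma(config: ExperimentConfig) -> CorrelationMatrix:
    if config.sigma_path:
        return read_matrix(config.sigma_path)
    return surrogate_sigma(
        config.surrogate_p, config.surrogate_target,
        seed=child_seed(config.seed, "sigma"),
    )


class _ESSCalibrator:
    """Caches the null MPPI threshold per (prior regime, sampler settings)."""

    def __init__(self, config: ExperimentConfig, sigma: CorrelationMatrix):
        self.config = config
        self.sigma = sigma
        self._cache: dict[tuple, float] = {}

    def threshold(self, ess_config: ESSConfig) -> float:
        key = (ess_config.prior_model_size, ess_config.prior_size_variance,
               ess_config.n_iter, ess_config.n_chains, self.config.n)
        if key not in self._cache:
            thr = mppi_null_threshold(
                self.sigma, self.config.n, ess_config,
                n_null_runs=self.config.ess_null_runs,
                seed=child_seed(self.config.seed, "ess-null"),
            )
            log.info("ESS null MPPI threshold %.4f for prior E=%s rho=%s",
                     thr, key[0], key[1])
            self._cache[key] = thr
        return self._cache[key]


def _method_selector(name: str, params: dict, k: int, seed: int,
                     calibrator: _ESSCalibrator | None):
    params = dict(params)
    if name == "GUESS":
        ess = ESSConfig.for_k(k, **{
            f: params.pop(f) for f in
            ("n_iter", "burn_in", "n_chains", "temperature_ratio", "g",
             "max_model_size", "posterior_model_threshold")
            if f in params
        })
        if "mppi_threshold" not in params and calibrator is not None:
            params["mppi_threshold"] = calibrator.threshold(ess)
        params.update(
            n_iter=ess.n_iter, burn_in=ess.burn_in, n_chains=ess.n_chains,
            prior_model_size=ess.prior_model_size,
            prior_size_variance=ess.prior_size_variance,
            posterior_model_threshold=ess.posterior_model_threshold,
            temperature_ratio=ess.temperature_ratio, g=ess.g,
            max_model_size=ess.max_model_size,
        )
    est = make_selector(name, **params)
    if hasattr(est, "random_state"):
        est.set_params(random_state=seed)
    return est


def score_methods(
    dataset: SimulatedDataset,
    methods: dict[str, dict],
    k: int,
    run_key: tuple,
    master_seed: int,
    calibrator: _ESSCalibrator | None = None,
) -> list[dict]:
    """Fit every configured method on one shared dataset and score it."""
    records = []
    for name, params in methods.items():
        seed = child_seed(master_seed, *run_key, name)
        base = {"scenario_set": run_key[0], "k": k, "run": run_key[2],
                "method": name, "seed": seed, "failed": False, "error": ""}
        try:
            est = _method_selector(name, params, k, seed, calibrator)
            result = est.fit(dataset.X, dataset.y).to_result()
            rec = score_run(dataset, result)
            base.update(rec.as_dict())
            base["n_selected"] = result.n_selected
        except Exception as exc:  # noqa: BLE001 - a failed run is a recorded outcome
            log.warning("method %s failed on %s: %s", name, run_key, exc)
            base["failed"] = True
            base["error"] = f"{type(exc).__name__}: {exc}"
            for stat in PerformanceRecord.__dataclass_fields__:
                base[stat] = float("nan")
            base["n_selected"] = float("nan")
        records.append(base)
    return records


def _one_run(config, sigma, raw, calibrator, set_id, k, run) -> list[dict]:
    spec = scenario(set_id, k, n=config.n, p=sigma.p, **config.scenario_overrides)
    seed = child_seed(config.seed, set_id, k, run)
    dataset = simulate_run(spec, sigma, seed=seed, raw_table=raw)
    return score_methods(dataset, config.methods, k, (set_id, k, run),
                         config.seed, calibrator)


def run_experiment(config: ExperimentConfig,
                   sigma: CorrelationMatrix | None = None) -> Iterator[dict]:
    """Execute the experiment, yielding one record per (scenario, run, method).

    Records are persisted incrementally to ``output_dir/records.csv`` when an
    output directory is configured; completed (set, k, run) keys found there
    are skipped, making interrupted experiments resumable.
    """
    sigma = sigma if sigma is not None else load_sigma(config)
    raw = None
    if config.raw_exposures_path:
        raw = pd.read_csv(config.raw_exposures_path).to_numpy(dtype=float)
    calibrator = _ESSCalibrator(config, sigma) if "GUESS" in config.methods else None
    if calibrator is not None:
        # warm the cache up front so parallel workers share it
        for k in sorted(set(config.k_values)):
            calibrator.threshold(ESSConfig.for_k(
                k, **{f: v for f, v in config.methods["GUESS"].items()
                      if f in ("n_iter", "burn_in", "n_chains")}))

    out_path = done = None
    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "records.csv"
        done = set()
        if out_path.exists():
            prev = pd.read_csv(out_path)
            done = set(map(tuple, prev[["scenario_set", "k", "run"]].to_numpy()))
            log.info("resuming: %d completed run keys found", len(done))

    keys = [
        (s, k, r)
        for s in config.scenario_sets
        for k in config.k_values
        for r in range(config.n_runs)
        if not done or (s, k, r) not in done
    ]
    jobs = (delayed(_one_run)(config, sigma, raw, calibrator, *key) for key in keys)
    parallel = Parallel(n_jobs=config.n_jobs, return_as="generator")
    for key, records in zip(keys, parallel(jobs)):
        log.info("scenario set %d, k=%d, run %d done", *key)
        if out_path is not None:
            pd.DataFrame(records).to_csv(
                out_path, mode="a", header=not out_path.exists(), index=False
            )
        yield from records


@dataclass(frozen=True)
class AggregateTable:
    """Summary statistics per method: per-scenario means and their spread."""

    per_scenario: pd.DataFrame   # (method, scenario_set, k) x statistic means
    across: pd.DataFrame         # method x (statistic, mean/min/max/se/p5/p95)

    def cell(self, method: str, stat: str) -> str:
        row = self.across.loc[method]
        return (f"{row[(stat, 'mean')]:.2f} "
                f"[{row[(stat, 'min')]:.2f};{row[(stat, 'max')]:.2f}]")


def aggregate(records: Iterable[dict] | pd.DataFrame,
              scope: str = "across_scenarios") -> AggregateTable:
    """Aggregate run records into study-style summaries.

    Per-scenario scope averages runs within each (method, scenario set, k)
    cell; the across-scenario table then reports mean/min/max (plus standard
    error and 5th/95th percentiles) of the per-scenario means.  Statistics
    that are undefined for k = 0 (sensitivity, FDP, the alternative metrics)
    are NaN there and drop out of the averages.
    """
    df = pd.DataFrame(list(records)) if not isinstance(records, pd.DataFrame) else records
    if df.empty:
        raise ValidationError("no records to aggregate")
    if "failed" in df:
        df = df[~df["failed"].astype(bool)]
    stats = [c for c in STAT_COLUMNS if c in df.columns]
    per = df.groupby(["method", "scenario_set", "k"])[stats].mean()
    if scope == "per_scenario":
        across = per.groupby("method").agg(["mean", "min", "max"])
    elif scope == "across_scenarios":
        def _summary(g: pd.DataFrame) -> pd.Series:
            out = {}
            for stat in stats:
                v = g[stat].dropna()
                out.update({
                    (stat, "mean"): v.mean(), (stat, "min"): v.min(),
                    (stat, "max"): v.max(),
                    (stat, "se"): v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                    (stat, "p5"): v.quantile(0.05), (stat, "p95"): v.quantile(0.95),
                })
            return pd.Series(out)

        across = per.groupby("method").apply(_summary, include_groups=False)
        across.columns = pd.MultiIndex.from_tuples(across.columns)
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    return AggregateTable(per_scenario=per.reset_index(), across=across)


def report(table: AggregateTable, output_dir: str | Path,
           formats: tuple[str, ...] = ("csv", "markdown")) -> list[Path]:
    """Write study-table-shaped summaries (CSV and/or markdown)."""
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    stats = [s for s in STAT_COLUMNS if (s, "mean") in table.across.columns]
    if "csv" in formats:
        path = out_dir / "table1.csv"
        flat = table.across.copy()
        flat.columns = [f"{stat}_{agg}" for stat, agg in flat.columns]
        flat.to_csv(path)
        table.per_scenario.to_csv(out_dir / "per_scenario.csv", index=False)
        written += [path, out_dir / "per_scenario.csv"]
    if "markdown" in formats:
        path = out_dir / "table1.md"
        lines = ["| Method | " + " | ".join(stats) + " |",
                 "|" + "---|" * (len(stats) + 1)]
        for method in table.across.index:
            cells = [table.cell(method, s) for s in stats]
            lines.append(f"| {method} | " + " | ".join(cells) + " |")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written


def save_run_summary(config: ExperimentConfig, sigma: CorrelationMatrix,
                     output_dir: str | Path) -> None:
    """Persist the config and sigma provenance next to the records."""
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "sigma_info.json").write_text(json.dumps({
        "p": sigma.p,
        "source": config.sigma_path or "surrogate",
    }, indent=2))
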