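# Methods

`exposobench` is a simulation benchmark for variable selection in
exposome-health association studies: many correlated exposure covariates, a
continuous outcome linearly driven by a small unknown subset of them, and
six linear-regression-based selection methods competing to recover that
subset.

## Generative model

Exposure rows are i.i.d. draws from a mean-centered multivariate normal,
`X ~ N(0, Σ)`, with `Σ` a `p × p` correlation matrix (`p = 237` by
default).  Five columns are dichotomized into 0/1 indicators to emulate
binary questionnaire items; the cut points reproduce configurable
positive-response proportions (defaults `0.1, 0.25, 0.5, 0.75, 0.9`, spread
evenly across columns — the real cohort proportions are not public, so
these are a deliberate spread covering rare through common responses).

The outcome is

```
y = X β + e,   e ~ N(0, σ²I),
```

with `β_i = 1` on `k` randomly drawn true predictors and 0 elsewhere
(`k ∈ {0, 1, 2, 3, 5, 10, 25}`).  The residual variance is calibrated in
closed form so the true predictors explain `R² = 0.03·k` of the outcome
variance: with signal variance `v = βᵀΣβ`,

```
σ² = v (1 − R²) / R².
```

This keeps the signal-to-noise ratio per predictor constant across
scenarios.  Two conventions: for `k = 0` the constraint degenerates and
`σ² = 1`; the signal variance is always computed on the latent Gaussian
scale even when a true predictor is dichotomized, which keeps `σ²`
closed-form and identical across runs of a scenario (the realized R² for a
binary true predictor is then slightly below target — a property of the
data, not a bug of the calibration).

Seven scenario sets vary one ingredient at a time: (1) baseline; (2)/(3)
true predictors constrained to pairwise `|r| < 0.2` / `> 0.5` on `Σ`
(rejection sampling, checked on `Σ` itself, not on sample correlations);
(4)/(5) exposures drawn from `Σ⁻` (off-diagonals halved) / `Σ⁺`
(off-diagonals doubled, capped at 1, repaired to positive semidefinite);
(6) exposures bootstrapped from a user-supplied raw table instead of
Gaussian draws (columns re-centered); (7) effect sizes `U[0.5, 1.5]`
instead of all 1.

## Correlation structure

`CorrelationMatrix` enforces symmetry (1e-10), unit diagonal, entries in
[−1, 1] and smallest eigenvalue ≥ −1e-8.  Indefinite inputs are repaired by
Higham-style alternating projections (PSD cone ↔ unit-diagonal set, with
Dykstra's correction; convergence when successive iterates differ by
< 1e-9 Frobenius), which converges to the nearest correlation matrix in
Frobenius norm and is idempotent on valid inputs.

When no deposited matrix is available, `surrogate_sigma` generates one
matching two printed summary targets within ±3 percentage points: the
proportion of unordered off-diagonal pairs with `|r| < 0.2` (target 0.83)
and the proportion of variables with at least one partner at `|r| > 0.6`
(target 0.78).  Construction: variables are partitioned into
moderate-correlation communities (within-community `r ~ U(0.30, 0.45)`,
sized so community pairs supply the |r| ≥ 0.2 mass), small high-correlation
cliques (`r ~ U(0.65, 0.85)`, sizes 2–3) are nested inside communities
until the strong-partner target is covered, one larger clique (~12
variables, emulating a homogeneous measurement panel such as congener
series) enables the strongly-correlated-predictor scenarios at larger `k`,
and everything else is weak background noise (`|r| ≤ 0.1`).  The result is
PSD-repaired, summarized, and regenerated (new substream) until the targets
are met.  This surrogate reproduces the two summary statistics, not the full
spectral or community structure of a real cohort matrix; conclusions that
depend on fine correlation structure (e.g. exact false-discovery levels of
univariate screening) shift by a few points relative to a real matrix.

## Selection methods

All six return the selected set `B`, a length-`p` coefficient vector that
is zero off `B`, and method diagnostics.  They share each simulated dataset
within a run.

- **EWAS** — one univariate OLS per covariate; two-sided slope p-values;
  selection by Benjamini-Hochberg FDR at 5% (benchmark), with
  Benjamini-Yekutieli, Bonferroni, permutation-based FDR (100 outcome
  permutations; largest p-value threshold whose estimated FDR —
  mean null count / observed count — stays ≤ 5%) and no correction as
  alternatives.  Constant covariates get p = 1 with a warning.
- **EWAS-MLR** — the EWAS hits enter one multiple OLS; hits with two-sided
  p < 5% there are retained with their stage-2 coefficients.  Exactly
  aliased columns are dropped deterministically (lowest index kept).
- **ENET** — elastic net over mixing proportions {0.1, …, 1.0} × 100
  log-spaced penalties (path down to 1e-3 of the null-model penalty),
  10-fold CV RMSE; chosen point = fewest nonzero coefficients among points
  within one standard error of the minimum RMSE; ties resolve to the
  stronger penalty, then the larger mixing proportion.  Covariates are
  standardized internally; coefficients return to the original scale.
- **sPLS** — iterative PLS components whose direction vectors are
  soft-thresholded (weights below a fraction η of the largest are shrunk to
  zero); the support of the retained components defines the selection, and
  coefficients come from a dense PLS refit restricted to that support
  (reference-implementation behavior), so they vanish exactly off the
  selection.  `K ∈ {0, …, 5}` (0 = intercept-only) and
  `η ∈ {0, 0.1, …, 0.9}` by minimum 5-fold CV RMSE; ties prefer fewer
  components, then stronger thresholds.
- **GUESS-style evolutionary stochastic search** — Gaussian regression with
  a Zellner g-prior (`g = n`) and a beta-binomial prior on model size with
  mean `E` and variance `ρ` (`E = 3, ρ = 3` for `k < 5`; `E = k + 2, ρ = 5`
  otherwise; if the requested variance is below the binomial ceiling an
  independent-inclusion binomial is used instead).  Three chains on a
  geometric temperature ladder (ratio 1.3); per iteration 70% mutation
  (add/remove/swap with Hastings correction), 15% uniform crossover between
  two random chains, 15% neighbor exchange.  20,000 iterations, 5,000
  burn-in at paper scale.  Posterior model probabilities are cold-chain
  visit frequencies after burn-in; models above 0.01 posterior are
  retained; the MPPI of a covariate is the retained-mass fraction of
  retained models containing it; selection thresholds the MPPI at the
  `1 − 0.05/p` quantile of MPPIs pooled over null-model runs (no covariate
  associated), estimated conservatively with the upper empirical quantile —
  the level sits deep in the pooled tail, so at least ~20 null runs are
  pooled by default.  Coefficients come from a ridge refit on the selected
  columns with a GCV-chosen penalty (intercept unpenalized via centering).
- **DSA** — greedy deletion/substitution/addition search over main-effects
  models, scored by residual sum of squares on the Gram matrix of the
  centered design (additions evaluated vectorized via the Schur
  complement); best model per size up to 40 is recorded; the final size
  minimizes 5-fold CV RMSE where the search is re-run inside every
  training fold (scoring full-data models on held-out folds would leak the
  selection and overfit pure noise); near-ties (relative 1e-8) favor the
  smaller model; equal-RSS moves resolve to the lowest variable index.
  Final coefficients are a full-data OLS refit.

## Performance statistics

For truth set `A` (size `k`) and selection `B` (size `n_B`):
sensitivity `|A∩B|/|A|`, specificity `|Aᶜ∖B|/|Aᶜ|`, false discovery
proportion `|B∖A|/|B|` (0 when `B` is empty); mean absolute bias
`mean|β̂ − β|` over all / true / unrelated covariates (unselected
covariates carry β̂ = 0); and the correlation-aware alternatives

```
AltSens = (1/k)  Σ_{a∈A} max_{b∈B} |r(a,b)|
AltFDP  = 1 − (1/n_B) Σ_{b∈B} max_{a∈A} |r(b,a)|
```

computed on the run's sample correlation matrix by default (`Σ`-based
variant available).  AltSens ≥ sensitivity and AltFDP ≤ FDP always; with
`B` empty both are set to 0, extending the FDP convention; with `k = 0`
sensitivity, FDP and the alternative metrics are NaN and drop out of
aggregates.  The extended protocol augments `B` with every covariate
correlated above a threshold α ∈ [0.6, 0.9] with some hit and recomputes
the classical metrics; augmentation is monotone in α.

Aggregation follows the study's table convention: runs are averaged within
each (method, scenario set, k) cell, and across-scenario summaries report
mean [min; max] (plus SE and 5th/95th percentiles) of those per-scenario
means.

## Problem sizes used by the test suite

Full reproduction (7 sets × 7 k × 100 runs × 6 methods at 20,000 sampler
iterations) is a cluster-scale computation.  The packaged checks run, as
the package's own verification scale: exact closed-form and property
suites; the univariate-screening summary at full scale (six k values × 100
runs on the surrogate Σ); a scaled-down multivariate comparison (six k
values × 3 runs, sampler at 5,000 iterations); and a smoke study at
`p = 50, n = 300, k ∈ {1, 3}` × 10 runs for the method-ordering checks.
Monte-Carlo spread at these scales is a few percentage points on the
averaged statistics.

## Known limitations

- The surrogate Σ matches two summary statistics of the printed structure,
  not the deposited matrix itself; statistics that are sensitive to the
  full correlation profile (notably the FDP of univariate screening) land
  within a few points of, but not exactly on, values obtained with the
  cohort-derived matrix.
- The evolutionary stochastic search is a faithful-in-spirit
  reimplementation (prior family, temperature ladder and move mix are
  standard choices, not a port of the reference C++ sampler); only the
  iteration/chain counts, prior means/variances and thresholds follow the
  study settings.
- No measurement error, interactions, or nonlinear terms are modeled, by
  design.
- Uniform-over-qualifying-subsets sampling of constrained true-predictor
  sets is approximated by rejection sampling with a sequential-growth
  fallback; for severely constrained designs (pairwise `|r| > 0.5` with
  large `k`) the distribution over qualifying subsets is approximately,
  not exactly, uniform.
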