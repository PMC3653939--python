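# Methods

## Scope and data model

The package analyses seed-addition experiments in which seeds of several
tree species are sown into small quadrats at multiples of each species'
ambient seed rain, and seedling counts are followed through repeated
censuses.  The observation unit is one quadrat × census
(`QuadratRecord`): identifiers (plot, station, quadrat, species),
treatment (augmentation multiple, seeds added), covariates (ambient seed
rain, conspecific adult density), census month and seedling count.
Datasets are tidy CSVs with exactly those columns; schema validation
rejects negative counts, sown seeds in controls, and seedling counts
that increase through time within a quadrat.

## Synthetic experiment generator

`synthetic.simulate_experiment` produces complete experiments with known
truth so that every downstream stage is testable without field data.

Design defaults mirror a large Afrotropical sowing design: 21 plots × 3
stations × 35 quadrats of 0.25 m² (5 species × 7 augmentation levels,
the 0 level being the control), augmentation multiples
{0, 25, 50, 100, 200, 500, 2000} of species-specific ambient rain, and
censuses every 3 months from month 3 to 24.  The five default species
profiles use measured mean seed rains of 0.10–0.58 seeds m⁻² yr⁻¹ and
adult densities of 0.57–3.96 stems ha⁻¹; the SDs attached to adult
density are plausible inventions (the field source reports only means).
Sown seed numbers are `round(multiple × rain × area)` with a floor of
one seed for non-control levels — one cannot sow fractional seeds, and
sowing zero would silently turn a treatment into a control.

Counts are generated as:

* total seed input `S = seeds_added + rain × area × window`, the ambient
  window defaulting to one year of rain (`ambient_window_years`, exposed
  as a config scalar because the accrual window is a modelling choice,
  not something the design fixes);
* first-census count `~ NB2(mean = e^u · P0·S/(1+P0·S/Rmax), shape k)`
  with plot effect `u ~ N(0, σ_plot²)` drawn once per plot.  The plot
  effect is multiplicative (log-scale) — the standard convention for
  count models, keeping means positive;
* later censuses by binomial thinning with survival probability
  `logistic(surv_intercept − surv_density_slope × count)`.  This
  mortality mechanism is generator plumbing: the analysis refits the
  recruitment curve per census rather than modelling survival, but the
  generator needs *some* mechanism, and a logistic density-dependent
  thinning produces both density-independent (slope 0) and
  density-dependent regimes.  Counts are non-increasing by construction.

Truth defaults: `P0 = 0.01`, `Rmax = 1.125` seedlings/quadrat
(4.5 m⁻²), `k = 1`, `σ_plot = 0.8`, survival intercept 1.9 (≈87% per
3-month interval, giving ≈35% survival from month 3 to 24) and slope
0.02.  `P0` and `Rmax` sit mid-range of values reported for tropical
tree seedlings; `k = 1` encodes the strong overdispersion typical of
seed-addition counts; `σ_plot = 0.8` makes between-plot variation a
dominant noise source, as observed in the field.

What the generator does *not* emulate: spatial autocorrelation within
plots, seed predation dynamics, secondary dispersal, species-specific
recruitment parameters (all species share one truth), or
census-to-census measurement error.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every feature of real data.

## Realized limitation

`quadrat_effect_size` implements `E = (treatment − control)/seeds_added`.
Plot-level aggregation uses the plot × species control mean (not
station-level means) as the reference, then averages treatment quadrats
within plot × species × level; the choice of plot-level controls follows
the aggregation to "a single plot-level effect size" and is noted as an
assumption.  Values outside [0, 1] are retained and flagged — clipping
would bias plot means.

The two GLMMs are:

* **binomial-logit** for per-seed recruitment: trials = seeds added,
  successes = `max(0, count − round(plot × species control mean))`,
  truncated at trials.  The success construction makes `E ≈ y/n`; it is
  a documented convention since nothing in the field description pins it
  down.
* **lognormal-Poisson** for counts: Poisson likelihood, log link, an
  observation-level normal deviate on the log mean absorbing
  overdispersion (its SD reported as `sd_obs`).

Fixed effects are standardized `log1p(augmentation multiple)` and
standardized conspecific density; random effects are quadrat, plot,
species and species × plot (effect model) or plot and species crossed
(count model).  Priors: `N(0, 100)` on fixed effects; `Uniform(0, 100)`
on random-effect **standard deviations**.  A uniform-on-precision
alternative is switchable (`McmcOptions.prior_on`); uniform-on-SD is the
default because it is better behaved with few groups.

Sampling is component-wise adaptive random-walk Metropolis within
Gibbs: single-site updates for fixed effects; jointly proposed,
per-group-accepted updates for random-effect blocks (valid because
groups are conditionally independent); exact Gibbs draws for the SDs
(with a flat SD prior the precision is `Gamma((n−1)/2, Σb²/2)`,
truncated at the prior bound); an exact Gibbs translation move between
each random-effect block and the intercept; and an
ancillarity-sufficiency interweaving (ASIS) re-draw of each SD in the
non-centered parameterization, which breaks the funnel between an SD
and its deviates.  Step sizes adapt toward 0.35–0.44 acceptance during
burn-in only.  Defaults are 3 chains × 50,000 burn-in × 25,000 draws;
tests and the analysis scripts run scaled down (3 × 500–2000).
Convergence is summarized by a split-chain Gelman-Rubin statistic
(duplicate or zero-variance chains are compared unsplit with a warning,
since they carry no between-chain information) and an
initial-positive-sequence effective sample size.

## Fundamental limitation

`nb_log_pmf` is the NB2 mass (`variance = μ + μ²/k`; small `k` = more
overdispersion, matching the convention in which `k → 0` adds
variance).  `marginal_loglik` integrates the plot random effect by
adaptive Gauss-Hermite quadrature: the per-plot log-integrand is concave
in `u`, so its mode is found by damped Newton steps with analytic first
and second derivatives, and 20 nodes (default) are recentred at the mode
and rescaled by the Laplace SD.  `σ_plot = 0` short-circuits to the
exact fixed-effects sum.  Against dense-grid trapezoid integration the
quadrature agrees to ~1e-11 on small instances, and doubling the node
count changes nothing at 1e-6 tolerance.

`fit_model` maximizes the marginal likelihood over transformed
parameters (`logit P0`, `log Rmax`, `log k`, `log σ_plot`, as applicable
to the variant) with L-BFGS-B from a deterministic multi-start lattice
(moment-based centre plus fixed offsets; 5 starts by default), bounds
wide on the transformed scale, and the `log σ` lower bound treated as
the degenerate no-random-effect case.  Free parameter counts are DD 4,
DI 3, NO_DI 3, SEED_ONLY 2, and `AIC = 2p − 2ℓ`.  Wald 95% intervals
come from a central-difference Hessian on the transformed scale,
back-transformed.  `converged` requires optimizer success plus either
agreement of two starts within 0.01 nats or a small projected gradient.
The seed-only and no-DI variants are fitted and reported but excluded
from the headline DD-vs-DI comparison, which is decided by AIC with a
margin of 4 (`compare_models` flags `distinguished`, breaks ties by the
canonical model order).

`S` for fitting is `seeds_added + rain × area × window`, the ambient
component taken from the dataset column (not estimated), with
`quadrat_area` and `ambient_window_years` as explicit arguments
defaulting to the standard design (0.25 m², one year).

## Limitation decomposition, crossovers, trends

`limitation_at` evaluates `L_S`, `L_DI`, `L_DD`, `L_E` from the fitted
DD parameters; infinite `Rmax` raises a decomposition-undefined error
(there is no saturation to remove).  Crossovers use the closed forms
`S* = Rmax` (seed vs establishment) and `S* = Rmax(1−P0)/P0` (DD vs DI);
bracketing root-finders are kept as a cross-check and agree to 1e-6
relative.  Curves default to a 200-point log-spaced grid spanning
0.01–2000 ambient multiples, and crossovers are reported both in seeds
per quadrat and ambient multiples.

Temporal trends are Pearson correlations of per-census quantities
against census month with a two-sided t test on `n − 2` df
(zero-variance series are flagged undefined rather than failing).  The
effect-size time slope uses a two-stage scheme — per-species OLS slopes
pooled by inverse variance — as a fully specified stand-in for a
random-intercept mixed model whose exact structure is not recoverable
from the field description; perfect-fit species receive a tiny floor
variance so exact linear data pool to the common slope, and a single
species falls back to plain OLS (noted in the result).

## Problem sizes and numerical tolerances

Simulation studies in the test suite use: model recovery at 21 plots ×
3 stations × 1 species (50 replicates per truth; saturating truth
`P0 = 0.05, Rmax = 1/quadrat`, half-saturation at 20 seeds against a
290-seed maximum input); parameter and crossover recovery at 21 plots ×
105 single-species quadrats each (50 replicates); GLMM calibration at
the full 5-species design (20 replicates, 3 chains × 1000/1000).  These
sizes give stable medians while keeping each study in the minutes
range.  Quadrature uses 12 nodes in simulation loops and 16–25
elsewhere; fits use 3 starts in loops, 5 otherwise.  Optimizer
tolerances are `ftol = 1e-12`, `gtol = 1e-6` on the transformed scale.

## Known limitations

* The Metropolis-within-Gibbs sampler mixes adequately for the designs
  tested but is far less efficient than HMC; very sparse data (few
  successes) lengthen the burn-in required.
* Wald intervals on back-transformed parameters can be poor near
  boundaries (`P0 → 0`, `σ_plot → 0`); profile or bootstrap intervals
  are out of scope.
* `Rmax` and hence the DD/DI crossover are weakly identified when the
  largest seed inputs do not exceed the half-saturation input
  `Rmax/P0`; recovery studies show ~17% median crossover error at the
  design scale, with occasional large outliers.
* The two-stage time-slope estimator understates between-species
  uncertainty relative to a full REML mixed model.
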