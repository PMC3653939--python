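# seedlim

Analysis of seed-addition experiments: how much of a tree community's
failure to recruit seedlings is due to seeds never arriving (**seed
limitation**) versus conditions that kill seeds and seedlings after they
arrive (**establishment limitation**)?  The package implements the two
complementary analyses used for large multi-species sowing experiments
in tropical forest, exercised end to end on synthetic data with known
ground truth.

## The models

**Realized limitation.**  For quadrats sown with `n` seeds at one
augmentation level, the per-seed recruitment effect size is

    E = (N_treatment − N_control) / n,

the number of new recruits per seed added, normalized by un-sown control
quadrats.  `E → 1` means complete seed limitation (every added seed
recruits); `E → 0` means complete establishment limitation.  Variation
in `E` with augmentation level, conspecific adult density, site and
species is modelled with hierarchical Bayesian GLMMs (binomial-logit for
per-seed recruitment, lognormal-Poisson for counts) fitted by an
adaptive Metropolis-within-Gibbs sampler with split-chain Gelman-Rubin
diagnostics.

**Fundamental limitation.**  Seedling counts `y` at total seed input
`S` (sown + ambient rain) follow a Beverton-Holt recruitment curve with
negative-binomial (NB2) error and a log-normal plot random effect:

    R(S) = P0 · S / (1 + P0 · S / Rmax),
    y ~ NB(mean = e^u · R(S), shape = k),   u ~ N(0, σ_plot²),

where `P0` is per-seed recruitment under density-independent mortality
only and `Rmax` the seedling density at seed saturation.  Four nested
variants (full DD; density-independent `R = P0·S`; no-DI-loss
`R = S/(1+S/Rmax)`; seed-only `R = S`) are fitted by maximum marginal
likelihood (adaptive Gauss-Hermite quadrature) and compared by AIC, a
difference of 4 distinguishing models.  Removing one process at a time
from the fitted curve gives the limitation strengths

    L_S  = Rmax − R(S)            (limitless seed supply)
    L_DI = S/(1+S/Rmax) − R(S)    (no density-independent loss, P0→1)
    L_DD = P0·S − R(S)            (no density dependence, Rmax→∞)
    L_E  = S − R(S)               (every seed recruits)

with closed-form crossovers: establishment limitation overtakes seed
limitation at `S* = Rmax`, and density-dependent losses overtake
density-independent ones at `S* = Rmax·(1−P0)/P0`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic experiment (21 plots × 3 stations × 35 quadrats, 5 species
sown at 0–2000× ambient seed rain, censuses every 3 months to 24
months; ground truth `P0 = 0.01`, `Rmax = 1.125`/quadrat = 4.5 m⁻²,
`k = 1`, `σ_plot = 0.8`):

```sh
python analysis/01_simulate.py          # writes results/dataset.csv
python analysis/02_effect_sizes.py
python analysis/04_fit_recruitment.py
python analysis/05_limitation_curves.py
python analysis/06_trends.py
```

prints, among other things:

```
mean effect size by census month:
   3 mo: E = 0.0105
  24 mo: E = 0.0053
pooled time slope: -0.00023 per month (t = -6.27, df = 4, ...)

census  3 mo: best = DD (delta to runner-up = 46.1, distinguished = True);
              DD: P0 = 0.0121, Rmax = 1.155/quadrat, k = 0.77, sigma_plot = 0.54
census 24 mo: best = DD (delta to runner-up = 39.6, distinguished = True);
              DD: P0 = 0.0059, Rmax = 0.394/quadrat, k = 1.12, sigma_plot = 0.54

census  3 mo: seed->establishment crossover at 13.8x ambient; DI->DD at 1131x ambient
census 24 mo: seed->establishment crossover at  4.7x ambient; DI->DD at  800x ambient

L_S: r = -0.993, t = -20.59, df = 6, p = 0.0000 (significant)
```

Read: per-seed recruitment is low and declines with time (establishment
limitation dominates); the density-dependent model is decisively
selected at every census and recovers the generating parameters at the
first census; seed limitation outweighs establishment limitation only
below ~5–14× ambient seed rain; density-dependent mortality takes over
from density-independent mortality only at many-hundred-fold seed
densities; and the strength of seed limitation declines significantly
through ontogeny.  `analysis/03_hierarchical_glmm.py` adds the Bayesian
posterior summaries for the same data.

The same stages are available as subcommands of the `seedlim` CLI
(`simulate`, `effects`, `glmm`, `fit`, `decompose`, `trends`, `run`) and
as plain library calls (`seedlim.simulate_experiment`,
`seedlim.fit_model`, `seedlim.limitation_curve`, ...).

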