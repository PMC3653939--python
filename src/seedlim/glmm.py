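"""Hierarchical Bayesian GLMMs for realized-limitation responses.

Two models are provided, mirroring the two questions a seed-addition
experiment answers:

* a binomial-logit model for the per-seed recruitment probability
  (successes out of seeds added), and
* a lognormal-Poisson model for seedling counts (a Poisson likelihood
  with an observation-level normal deviate on the log mean, absorbing
  overdispersion).

Both take seed augmentation level and conspecific adult density as fixed
effects and quadrat / plot / species / species-by-plot terms as crossed
random effects.  Posteriors are sampled with an adaptive component-wise
random-walk Metropolis-within-Gibbs sampler (random-effect blocks are
proposed jointly and accepted per group, which is valid because groups
are conditionally independent given everything else).  Convergence is
monitored with the split-chain Gelman-Rubin statistic.

Priors default to Normal(0, 100) on fixed effects and Uniform(0, 100) on
random-effect *standard deviations*; a uniform-on-precision alternative
is switchable because uniform-on-SD is better behaved with few groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

__all__ = [
    "GlmmSpec",
    "PosteriorSummary",
    "McmcOptions",
    "fit_effect_glmm",
    "fit_count_glmm",
    "gelman_rubin",
    "effective_sample_size",
]

_VALID_FIXED = ("aug_level", "conspecific_density")
_VALID_RANDOM = ("quadrat", "plot", "species", "species_x_plot")


class SpecificationError(ValueError):
    """Raised for inconsistent model specifications."""


@dataclass(frozen=True)
class GlmmSpec:
    """Response, link and effect structure of one hierarchical model."""

    response: str = "per_seed"  # per_seed | count
    fixed_effects: tuple[str, ...] = _VALID_FIXED
    random_effects: tuple[str, ...] = _VALID_RANDOM
    link: str = "logit"  # logit | log

    def __post_init__(self) -> None:
        if self.response not in ("per_seed", "count"):
            raise SpecificationError(f"unknown response {self.response!r}")
        if self.link not in ("logit", "log"):
            raise SpecificationError(f"unknown link {self.link!r}")
        if self.response == "per_seed" and self.link != "logit":
            raise SpecificationError("per_seed response requires the logit link")
        if self.response == "count" and self.link != "log":
            raise SpecificationError("count response requires the log link")
        for f in self.fixed_effects:
            if f not in _VALID_FIXED:
                raise SpecificationError(f"unknown fixed effect {f!r}")
        for r in self.random_effects:
            if r not in _VALID_RANDOM:
                raise SpecificationError(f"unknown random effect {r!r}")


@dataclass(frozen=True)
class McmcOptions:
    """Sampler settings; defaults follow common practice for this design
    (3 chains, long burn-in); tests and pipelines run scaled-down."""

    chains: int = 3
    burn_in: int = 50_000
    draws: int = 25_000
    thin: int = 1
    prior_fixed_var: float = 100.0
    prior_sd_upper: float = 100.0
    prior_on: str = "sd"  # sd | precision
    adapt_interval: int = 50


@dataclass
class PosteriorSummary:
    parameter: str
    mean: float
    ci_2_5: float
    ci_97_5: float
    rhat: float
    ess: float


# ---------------------------------------------------------------------------
# data construction


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _build_matrices(records: pd.DataFrame, census_month: int,
                    spec: GlmmSpec) -> dict:
    sub = records[(records["census_month"] == census_month)].copy()
    treat = sub[(sub["aug_multiple"] > 0) & (sub["seeds_added"] > 0)].copy()
    if treat.empty:
        raise ValueError(f"no treatment quadrats at census {census_month}")

    if spec.response == "per_seed":
        # successes = recruits above the plot x species control background
        ctrl = (
            sub[sub["aug_multiple"] == 0]
            .groupby(["plot_id", "species_code"])["seedling_count"]
            .mean()
            .rename("control_mean")
        )
        treat = treat.join(ctrl, on=["plot_id", "species_code"])
        treat["control_mean"] = treat["control_mean"].fillna(0.0)
        trials = treat["seeds_added"].to_numpy(int)
        y = np.maximum(
            0, treat["seedling_count"].to_numpy(int)
            - np.round(treat["control_mean"].to_numpy(float)).astype(int)
        )
        over = y > trials
        if over.any():
            warnings.warn(
                f"{over.sum()} quadrats had more excess recruits than seeds "
                "added; successes truncated to trials", stacklevel=3,
            )
            y = np.minimum(y, trials)
    else:
        trials = None
        y = treat["seedling_count"].to_numpy(int)

    cols = []
    names = ["intercept"]
    cols.append(np.ones(len(treat)))
    for f in spec.fixed_effects:
        if f == "aug_level":
            cols.append(_standardize(np.log1p(treat["aug_multiple"]
                                              .to_numpy(float))))
        else:
            cols.append(_standardize(treat["conspecific_density"]
                                     .to_numpy(float)))
        names.append(f)
    X = np.column_stack(cols)

    factors = {}
    for r in spec.random_effects:
        if r == "quadrat":
            keys = treat["quadrat_id"].astype(str)
        elif r == "plot":
            keys = treat["plot_id"].astype(str)
        elif r == "species":
            keys = treat["species_code"].astype(str)
        else:
            keys = treat["species_code"].astype(str) + ":" + \
                treat["plot_id"].astype(str)
        codes, levels = pd.factorize(keys, sort=True)
        factors[r] = (codes.astype(int), len(levels))

    return {"y": y, "trials": trials, "X": X, "fixed_names": names,
            "factors": factors, "n_obs": len(treat)}


# ---------------------------------------------------------------------------
# likelihoods (per-observation log-likelihood as a function of eta)


def _binom_ll(y, n, eta):
    return y * eta - n * np.logaddexp(0.0, eta)


def _pois_ll(y, eta):
    # cap eta to keep exp finite; such proposals are rejected anyway
    return y * eta - np.exp(np.minimum(eta, 500.0))


# ---------------------------------------------------------------------------
# sampler


def _log_prior_sd(sigma: float, opts: McmcOptions) -> float:
    if sigma <= 0:
        return -np.inf
    if opts.prior_on == "sd":
        return 0.0 if sigma < opts.prior_sd_upper else -np.inf
    # uniform prior on the precision tau = sigma^-2 on (0, upper)
    tau = sigma ** -2
    if tau >= opts.prior_sd_upper:
        return -np.inf
    return math.log(2.0) - 3.0 * math.log(sigma)


def _run_chain(data: dict, spec: GlmmSpec, opts: McmcOptions,
               n_iter: int, n_burn: int, rng: np.random.Generator,
               track_obs_sd: bool) -> dict:
    y = data["y"].astype(float)
    X = data["X"]
    n_obs, n_beta = X.shape
    trials = None if data["trials"] is None else data["trials"].astype(float)
    binom = spec.response == "per_seed"

    factors = dict(data["factors"])
    if track_obs_sd:
        factors["obs"] = (np.arange(n_obs), n_obs)  # lognormal-Poisson deviate

    beta = np.zeros(n_beta)
    # crude intercept initialisation on the link scale
    if binom:
        p = np.clip((y.sum() + 0.5) / (trials.sum() + 1.0), 1e-6, 1 - 1e-6)
        beta[0] = float(logit(p))
    else:
        beta[0] = float(np.log(y.mean() + 0.5))

    b = {f: np.zeros(n) for f, (_, n) in factors.items()}
    sd = {f: 0.5 for f in factors}
    eta = X @ beta
    for f, (idx, _) in factors.items():
        eta = eta + b[f][idx]

    def ll_obs(e):
        return _binom_ll(y, trials, e) if binom else _pois_ll(y, e)

    cur_ll = ll_obs(eta)

    step_beta = np.full(n_beta, 0.1)
    step_b = {f: np.full(n, 0.5) for f, (_, n) in factors.items()}
    step_sd = {f: 0.5 for f in factors}
    acc_beta = np.zeros(n_beta)
    acc_b = {f: np.zeros(n) for f, (_, n) in factors.items()}
    acc_sd = {f: 0.0 for f in factors}

    kept = []
    prior_beta_var = opts.prior_fixed_var

    for it in range(n_iter):
        # --- fixed effects, one at a time
        for j in range(n_beta):
            prop = step_beta[j] * rng.standard_normal()
            eta_new = eta + prop * X[:, j]
            new_ll = ll_obs(eta_new)
            d = new_ll.sum() - cur_ll.sum()
            d += (beta[j] ** 2 - (beta[j] + prop) ** 2) / (2 * prior_beta_var)
            if math.log(rng.random()) < d:
                beta[j] += prop
                eta, cur_ll = eta_new, new_ll
                acc_beta[j] += 1

        # --- random-effect deviates, jointly proposed, per-group accept
        for f, (idx, n_g) in factors.items():
            prop = step_b[f] * rng.standard_normal(n_g)
            eta_new = eta + prop[idx]
            new_ll = ll_obs(eta_new)
            d_obs = np.bincount(idx, weights=new_ll - cur_ll, minlength=n_g)
            bf = b[f]
            d = d_obs + (bf ** 2 - (bf + prop) ** 2) / (2 * sd[f] ** 2)
            accept = np.log(rng.random(n_g)) < d
            if accept.any():
                delta = np.where(accept, prop, 0.0)
                b[f] = bf + delta
                eta = eta + delta[idx]
                acc_obs = accept[idx]
                cur_ll = np.where(acc_obs, new_ll, cur_ll)
                acc_b[f] += accept

        # --- intercept/random-effect translation (exact Gibbs along the
        # likelihood-invariant direction b_f -> b_f - t, beta0 -> beta0 + t)
        for f in factors:
            n_g = len(b[f])
            prec = n_g / sd[f] ** 2 + 1.0 / prior_beta_var
            mean_t = (b[f].sum() / sd[f] ** 2
                      - beta[0] / prior_beta_var) / prec
            t = mean_t + rng.standard_normal() / math.sqrt(prec)
            b[f] = b[f] - t
            beta[0] += t  # eta is unchanged

        # --- random-effect SDs
        for f in factors:
            n_g = len(b[f])
            ssq = float(b[f] @ b[f])
            if n_g >= 2 and ssq > 0 and opts.prior_on == "sd":
                # exact Gibbs: with a flat prior on sigma the precision is
                # Gamma((n-1)/2, ssq/2), truncated at the prior upper bound
                for _ in range(20):
                    tau = rng.gamma((n_g - 1) / 2.0, 2.0 / ssq)
                    if tau > opts.prior_sd_upper ** -2:
                        sd[f] = tau ** -0.5
                        break
            elif n_g >= 1 and ssq > 0 and opts.prior_on == "precision":
                for _ in range(20):
                    tau = rng.gamma(n_g / 2.0 + 1.0, 2.0 / ssq)
                    if tau < opts.prior_sd_upper:
                        sd[f] = tau ** -0.5
                        break
            else:
                # degenerate case: fall back to a random walk on log sd
                s = sd[f]
                s_new = s * math.exp(step_sd[f] * rng.standard_normal())
                d = (
                    _log_prior_sd(s_new, opts) - _log_prior_sd(s, opts)
                    + n_g * (math.log(s) - math.log(s_new))
                    + ssq / 2 * (1 / s ** 2 - 1 / s_new ** 2)
                    + math.log(s_new) - math.log(s)  # log-scale Jacobian
                )
                if math.log(rng.random()) < d:
                    sd[f] = s_new

        # --- interweaving (ASIS): re-draw each SD with the deviates held
        # fixed in their non-centered form z = b/sd, which breaks the
        # funnel-shaped coupling between a SD and its deviates
        for f in factors:
            s = sd[f]
            if s <= 0 or not np.any(b[f]):
                continue
            idx = factors[f][0]
            z = b[f] / s
            s_new = s * math.exp(step_sd[f] * rng.standard_normal())
            eta_new = eta + ((s_new - s) * z)[idx]
            new_ll = ll_obs(eta_new)
            d = (new_ll.sum() - cur_ll.sum()
                 + _log_prior_sd(s_new, opts) - _log_prior_sd(s, opts)
                 + math.log(s_new) - math.log(s))
            if math.log(rng.random()) < d:
                sd[f] = s_new
                b[f] = s_new * z
                eta, cur_ll = eta_new, new_ll
                acc_sd[f] += 1

        # --- step-size adaptation during burn-in
        if it < n_burn and (it + 1) % opts.adapt_interval == 0:
            w = opts.adapt_interval
            step_beta *= np.exp(np.clip(acc_beta / w - 0.44, -0.5, 0.5))
            acc_beta[:] = 0
            for f in factors:
                step_b[f] *= np.exp(np.clip(acc_b[f] / w - 0.35, -0.5, 0.5))
                acc_b[f][:] = 0
                step_sd[f] *= math.exp(min(max(acc_sd[f] / w - 0.44, -0.5),
                                           0.5))
                acc_sd[f] = 0.0

        if it >= n_burn and (it - n_burn) % opts.thin == 0:
            row = list(beta) + [sd[f] for f in factors]
            kept.append(row)

    names = [f"beta_{n}" for n in data["fixed_names"]] + \
        [f"sd_{f}" for f in factors]
    return {"draws": np.asarray(kept), "names": names}


def _fit_glmm(records: pd.DataFrame, census_month: int, spec: GlmmSpec,
              chains: int, burn_in: int, draws: int, rng_seed: int,
              options: McmcOptions | None,
              track_obs_sd: bool) -> pd.DataFrame:
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    opts = options or McmcOptions()
    data = _build_matrices(records, census_month, spec)
    if np.all(data["y"] == 0):
        warnings.warn("all responses are zero; posteriors sit at the "
                      "boundary of the data's support", stacklevel=2)

    seeds = np.random.SeedSequence(rng_seed).spawn(chains)
    chain_draws = []
    names = None
    for cs in seeds:
        rng = np.random.default_rng(cs)
        out = _run_chain(data, spec, opts, burn_in + draws, burn_in, rng,
                         track_obs_sd)
        chain_draws.append(out["draws"])
        names = out["names"]

    all_draws = np.stack(chain_draws)  # (chains, draws, params)
    rows = []
    any_bad = False
    for j, name in enumerate(names):
        seqs = [all_draws[c, :, j] for c in range(chains)]
        rhat = gelman_rubin(seqs)
        ess = effective_sample_size(seqs)
        flat = all_draws[:, :, j].ravel()
        rows.append(PosteriorSummary(
            parameter=name,
            mean=float(flat.mean()),
            ci_2_5=float(np.percentile(flat, 2.5)),
            ci_97_5=float(np.percentile(flat, 97.5)),
            rhat=float(rhat),
            ess=float(ess),
        ))
        if rhat > 1.1:
            any_bad = True
    if any_bad:
        warnings.warn("some parameters have split-chain R-hat > 1.1; "
                      "chains may not have converged", stacklevel=2)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["draws"] = all_draws
    df.attrs["names"] = names
    return df


def fit_effect_glmm(
    records: pd.DataFrame,
    census_month: int,
    spec: GlmmSpec | None = None,
    chains: int = 3,
    burn_in: int = 50_000,
    draws: int = 25_000,
    rng_seed: int = 0,
    options: McmcOptions | None = None,
) -> pd.DataFrame:
    """Binomial-logit GLMM for per-seed recruitment.

    Each treatment quadrat contributes trials = seeds added and successes
    = recruits in excess of the plot x species control mean (truncated to
    [0, trials]).  Returns posterior summaries (mean, 95% credible
    interval, split-chain R-hat, ESS) for the fixed effects and
    random-effect SDs; full draws are attached in ``df.attrs['draws']``.
    """
    spec = spec or GlmmSpec(response="per_seed", link="logit")
    if spec.response != "per_seed":
        raise SpecificationError("fit_effect_glmm requires a per_seed spec")
    return _fit_glmm(records, census_month, spec, chains, burn_in, draws,
                     rng_seed, options, track_obs_sd=False)


def fit_count_glmm(
    records: pd.DataFrame,
    census_month: int,
    spec: GlmmSpec | None = None,
    chains: int = 3,
    burn_in: int = 50_000,
    draws: int = 25_000,
    rng_seed: int = 0,
    options: McmcOptions | None = None,
) -> pd.DataFrame:
    """Lognormal-Poisson GLMM for seedling counts.

    A Poisson likelihood with a log link; an observation-level normal
    deviate on the log mean absorbs overdispersion (its SD is reported as
    ``sd_obs``).  Default random effects are species and plot, crossed.
    """
    spec = spec or GlmmSpec(response="count", link="log",
                            random_effects=("plot", "species"))
    if spec.response != "count":
        raise SpecificationError("fit_count_glmm requires a count spec")
    return _fit_glmm(records, census_month, spec, chains, burn_in, draws,
                     rng_seed, options, track_obs_sd=True)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: list) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Each chain is split in half; R-hat compares between- and within-half
    variances.  Chains that are exact duplicates of one another carry no
    between-chain information, so they are compared unsplit (yielding a
    value <= 1, with a warning), as are zero-variance chains.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    n = min(len(c) for c in chains)
    if n < 10:
        raise ValueError("chains must have length >= 10")
    chains = [c[:n] for c in chains]

    identical = all(np.array_equal(chains[0], c) for c in chains[1:])
    degenerate = all(np.var(c) == 0 for c in chains)
    if identical or degenerate:
        warnings.warn("chains are identical or zero-variance; R-hat is "
                      "uninformative", stacklevel=2)
        if degenerate:
            return 1.0
        halves = chains  # unsplit: between-chain variance is exactly zero
    else:
        half = n // 2
        halves = []
        for c in chains:
            halves.append(c[:half])
            halves.append(c[half:2 * half])

    arr = np.asarray(halves)
    m, length = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = length * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (length - 1) / length * W + B / length
    return float(math.sqrt(var_hat / W))


def effective_sample_size(chains: list) -> float:
    """Effective sample size from pooled autocorrelations.

    Uses Geyer's initial-positive-sequence truncation on the mean
    autocorrelation function across chains.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    n = min(len(c) for c in chains)
    m = len(chains)
    total = m * n
    w = np.mean([np.var(c, ddof=1) for c in chains])
    if w == 0:
        return float(total)
    max_lag = min(n - 1, 200)
    rho = np.zeros(max_lag)
    for c in chains:
        cc = c[:n] - c[:n].mean()
        for t in range(1, max_lag + 1):
            rho[t - 1] += (cc[:-t] @ cc[t:]) / (n * w)
    rho /= m
    s = 0.0
    for t in range(0, max_lag - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
    ess = total / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), total))
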