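"""Shared simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

import seedlim as sl


def single_species_design(n_plots=21, stations_per_plot=3, code="MAMA",
                          rain=0.58):
    """Design with one focal species (defaults to the highest-rain one)."""
    sp = (sl.SpeciesProfile(code, rain, 1.67, 0.8),)
    return sl.ExperimentDesign(n_plots=n_plots,
                               stations_per_plot=stations_per_plot,
                               species=sp)


def simulate_logit_records(design, beta0, beta_aug, sig_sp, sig_plot,
                           sig_q, sig_sxp, seed):
    """Census table whose treatment counts follow a known binomial-logit
    GLMM (used for calibration studies of the hierarchical model)."""
    base = sl.simulate_experiment(design, sl.TrueParams(), seed)
    df = base[base.census_month == 3].copy().reset_index(drop=True)
    rng = np.random.default_rng(seed + 1)
    treat = df[(df.aug_multiple > 0) & (df.seeds_added > 0)]
    x = np.log1p(treat.aug_multiple.to_numpy(float))
    x = (x - x.mean()) / x.std()
    sp_codes, sp_lv = pd.factorize(treat.species_code, sort=True)
    pl_codes, pl_lv = pd.factorize(treat.plot_id, sort=True)
    sxp_codes, sxp_lv = pd.factorize(
        treat.species_code + ":" + treat.plot_id, sort=True)
    eta = (beta0 + beta_aug * x
           + rng.normal(0, sig_sp, len(sp_lv))[sp_codes]
           + rng.normal(0, sig_plot, len(pl_lv))[pl_codes]
           + rng.normal(0, sig_sxp, len(sxp_lv))[sxp_codes]
           + rng.normal(0, sig_q, len(treat)))
    ycount = rng.binomial(treat.seeds_added.to_numpy(int), expit(eta))
    df["seedling_count"] = 0
    df.loc[treat.index, "seedling_count"] = ycount
    return df


def tiny_records(n_plots=3, n_q=4, seed=1, census_month=3):
    """Small arbitrary census table for likelihood oracles."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plots):
        for q in range(n_q):
            rows.append(dict(
                plot_id=f"P{p}", station_id="s", quadrat_id=f"P{p}Q{q}",
                species_code="X", aug_multiple=1.0,
                seeds_added=int(rng.uniform(1, 200)),
                ambient_seed_rain=0.2, conspecific_density=1.0,
                census_month=census_month,
                seedling_count=int(rng.poisson(2)),
            ))
    return pd.DataFrame(rows)


def dense_grid_marginal_loglik(records, params, model="DD", census_month=3,
                               n_grid=100_001, width_sd=8.0):
    """Brute-force trapezoid integration over the plot random effect.

    Independent oracle for the adaptive-quadrature marginal likelihood:
    integrates the NB likelihood against the normal density on a dense
    u-grid, one plot at a time.
    """
    from scipy.special import logsumexp
    from seedlim.recruitment import Model, _PlotData, _model_mean, nb_log_pmf

    data = _PlotData.from_records(records, census_month)
    model = Model(model)
    sigma = params.sigma_plot
    total = 0.0
    u = np.linspace(-width_sd * sigma, width_sd * sigma, n_grid)
    w = np.full(n_grid, u[1] - u[0])
    w[0] /= 2
    w[-1] /= 2
    log_phi = (-0.5 * u ** 2 / sigma ** 2 - np.log(sigma)
               - 0.5 * np.log(2 * np.pi))
    for i in range(len(data.plots)):
        S = data.S[i][data.mask[i]]
        y = data.y[i][data.mask[i]]
        m = _model_mean(S, model, params.P0, params.Rmax)
        ll = nb_log_pmf(y[None, :], np.exp(u)[:, None] * m[None, :],
                        params.k).sum(axis=1)
        total += logsumexp(ll + log_phi, b=w)
    return float(total)
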