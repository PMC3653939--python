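"""Synthetic seed-addition experiments with known ground truth.

Emulates a large-scale tropical seed-sowing design: permanent vegetation
plots each hold a few sowing stations; every station carries one quadrat
per species x augmentation-level combination (the zero level being the
un-sown control).  Seeds are sown once at multiples of each species'
ambient annual seed rain; seedlings are censused every three months for
two years.

Counts at the first census follow a Beverton-Holt mean with a
multiplicative log-normal plot effect and negative-binomial (NB2)
dispersion; later censuses are obtained by binomial thinning with a
density-dependent logistic survival probability, so counts can only
decrease through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesProfile",
    "ExperimentDesign",
    "TrueParams",
    "DEFAULT_SPECIES",
    "default_design",
    "default_truth",
    "build_design",
    "seeds_for_level",
    "simulate_experiment",
    "DATASET_COLUMNS",
]

#: canonical column order of the tidy per-quadrat census table
DATASET_COLUMNS = [
    "plot_id",
    "station_id",
    "quadrat_id",
    "species_code",
    "aug_multiple",
    "seeds_added",
    "ambient_seed_rain",
    "conspecific_density",
    "census_month",
    "seedling_count",
]


class ConfigurationError(ValueError):
    """Raised for invalid experimental-design configuration."""


class ParameterError(ValueError):
    """Raised for invalid ground-truth parameters."""


@dataclass(frozen=True)
class SpeciesProfile:
    """One focal species: ambient seed rain and adult conspecific density.

    Parameters
    ----------
    code
        Short species identifier (e.g. a four-letter code).
    ambient_seed_rain
        Mean natural seed rain, seeds m^-2 yr^-1.  Must be positive.
    conspecific_density_mean, conspecific_density_sd
        Mean and SD of adult (>10 cm dbh) conspecific density, stems ha^-1,
        used to draw a plot-level covariate.
    """

    code: str
    ambient_seed_rain: float
    conspecific_density_mean: float = 2.0
    conspecific_density_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.ambient_seed_rain <= 0:
            raise ConfigurationError(
                f"ambient_seed_rain must be > 0 for species {self.code!r}"
            )
        if self.conspecific_density_mean < 0 or self.conspecific_density_sd < 0:
            raise ConfigurationError("conspecific densities must be >= 0")


# Five focal species: mean seed rain (seeds m^-2 yr^-1) and mean adult
# conspecific density (stems ha^-1) from two years of seed-trap and
# vegetation-plot monitoring.  Density SDs are plausible inventions.
DEFAULT_SPECIES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("ENUT", 0.10, 1.17, 0.6),
    SpeciesProfile("PALA", 0.20, 2.37, 1.2),
    SpeciesProfile("STKA", 0.26, 0.57, 0.3),
    SpeciesProfile("MYAR", 0.53, 3.96, 2.0),
    SpeciesProfile("MAMA", 0.58, 1.67, 0.8),
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the seed-addition experiment.

    Defaults follow the field design: 21 one-hectare plots with 3 sowing
    stations each (63 stations), 0.5 x 0.5 m quadrats (0.25 m^2),
    augmentation multiples {0, 25, 50, 100, 200, 500, 2000} of ambient
    seed rain, censuses every 3 months from month 3 to month 24.

    ``ambient_window_years`` scales how much natural seed rain accrues in
    a quadrat over the experiment (1.0 = one full year of rain); it is a
    config scalar because the accrual window is a modelling choice.
    """

    n_plots: int = 21
    stations_per_plot: int = 3
    quadrat_area: float = 0.25
    aug_multiples: tuple[float, ...] = (0, 25, 50, 100, 200, 500, 2000)
    census_months: tuple[int, ...] = (3, 6, 9, 12, 15, 18, 21, 24)
    species: tuple[SpeciesProfile, ...] = DEFAULT_SPECIES
    ambient_window_years: float = 1.0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.stations_per_plot < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.quadrat_area <= 0:
            raise ConfigurationError("quadrat_area must be > 0")
        if not self.species:
            raise ConfigurationError("species list must be non-empty")
        aug = tuple(self.aug_multiples)
        if len(aug) < 2 or aug[0] != 0:
            raise ConfigurationError("aug_multiples must start with the 0 control")
        if any(b <= a for a, b in zip(aug, aug[1:])):
            raise ConfigurationError("aug_multiples must be strictly increasing")
        cm = tuple(self.census_months)
        if not cm or cm[0] < 3 or any(b <= a for a, b in zip(cm, cm[1:])):
            raise ConfigurationError(
                "census_months must be strictly increasing with first >= 3"
            )

    @property
    def n_stations(self) -> int:
        return self.n_plots * self.stations_per_plot

    @property
    def quadrats_per_station(self) -> int:
        return len(self.species) * len(self.aug_multiples)


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth recruitment and mortality parameters.

    ``P0`` is the per-seed recruitment probability under density-independent
    mortality only; ``Rmax`` the seed-saturated seedling count per quadrat;
    ``k`` the NB2 overdispersion (variance = mu + mu^2/k, small k = more
    overdispersion); ``sigma_plot`` the SD of the log-scale plot effect.
    ``surv_intercept``/``surv_density_slope`` give the between-census
    survival log-odds ``surv_intercept - surv_density_slope * count``;
    they are generator-side plumbing for mortality, not part of the
    recruitment model that is fitted downstream.
    """

    P0: float = 0.01
    Rmax: float = 1.125  # seedlings per 0.25 m^2 quadrat (= 4.5 m^-2)
    k: float = 1.0
    sigma_plot: float = 0.8
    surv_intercept: float = 1.9
    surv_density_slope: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.P0 <= 1):
            raise ParameterError("P0 must lie in (0, 1]")
        if not (self.Rmax > 0):
            raise ParameterError("Rmax must be > 0")
        if not (self.k > 0):
            raise ParameterError("k must be > 0")
        if self.sigma_plot < 0:
            raise ParameterError("sigma_plot must be >= 0")
        if self.surv_density_slope < 0:
            raise ParameterError("surv_density_slope must be >= 0")
        if not np.isfinite(self.surv_intercept):
            raise ParameterError("surv_intercept must be finite")


def default_design(**overrides) -> ExperimentDesign:
    return ExperimentDesign(**overrides)


def default_truth(**overrides) -> TrueParams:
    return TrueParams(**overrides)


def build_design(
    n_plots: int = 21,
    stations_per_plot: int = 3,
    quadrat_area: float = 0.25,
    aug_multiples: Sequence[float] = (0, 25, 50, 100, 200, 500, 2000),
    census_months: Sequence[int] = (3, 6, 9, 12, 15, 18, 21, 24),
    species: Sequence[SpeciesProfile] = DEFAULT_SPECIES,
    ambient_window_years: float = 1.0,
) -> ExperimentDesign:
    """Validate and assemble an :class:`ExperimentDesign`.

    Every station receives one quadrat per species x augmentation-level
    combination, the 0 level acting as that species' control quadrats.
    """
    return ExperimentDesign(
        n_plots=n_plots,
        stations_per_plot=stations_per_plot,
        quadrat_area=quadrat_area,
        aug_multiples=tuple(aug_multiples),
        census_months=tuple(census_months),
        species=tuple(species),
        ambient_window_years=ambient_window_years,
    )


def seeds_for_level(
    aug_multiple: float, ambient_seed_rain: float, quadrat_area: float
) -> int:
    """Number of seeds sown for one augmentation level.

    The sown count is ``round(aug_multiple * ambient_seed_rain *
    quadrat_area)``; when the product falls below one for a non-control
    level, a single seed is sown anyway (one cannot sow a fraction of a
    seed, and sowing zero would silently turn a treatment into a control).
    """
    if aug_multiple < 0 or ambient_seed_rain < 0 or quadrat_area < 0:
        raise ValueError("seeds_for_level arguments must be non-negative")
    if aug_multiple == 0:
        return 0
    target = aug_multiple * ambient_seed_rain * quadrat_area
    return max(1, int(round(target)))


def _survival_prob(count: np.ndarray, truth: TrueParams) -> np.ndarray:
    logit = truth.surv_intercept - truth.surv_density_slope * count
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_experiment(
    design: ExperimentDesign,
    truth: TrueParams,
    rng_seed: int,
) -> pd.DataFrame:
    """Simulate a complete census table for one experiment.

    Per quadrat the total seed input is ``S = seeds_added + ambient``,
    where ambient = rain x area x accrual window (controls receive ambient
    rain too).  The first-census count is negative-binomial with mean
    ``exp(u_plot) * P0 * S / (1 + P0 * S / Rmax)`` and shape ``k``,
    ``u_plot ~ N(0, sigma_plot^2)``.  Each subsequent census applies
    binomial thinning with survival probability
    ``logistic(surv_intercept - surv_density_slope * count)``.

    Returns a tidy DataFrame with :data:`DATASET_COLUMNS`, one row per
    quadrat x census, deterministic in ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    n_sp = len(design.species)
    n_lv = len(design.aug_multiples)

    u_plot = rng.normal(0.0, truth.sigma_plot, size=design.n_plots)
    # plot-level adult conspecific density per species (truncated at 0)
    dens = np.empty((design.n_plots, n_sp))
    for j, sp in enumerate(design.species):
        dens[:, j] = np.clip(
            rng.normal(sp.conspecific_density_mean, sp.conspecific_density_sd,
                       size=design.n_plots),
            0.0, None,
        )

    rows: dict[str, list] = {c: [] for c in DATASET_COLUMNS}
    for p in range(design.n_plots):
        plot_id = f"P{p + 1:02d}"
        for s in range(design.stations_per_plot):
            station_id = f"{plot_id}S{s + 1}"
            q_idx = 0
            for j, sp in enumerate(design.species):
                ambient = (
                    sp.ambient_seed_rain
                    * design.quadrat_area
                    * design.ambient_window_years
                )
                for m in design.aug_multiples:
                    q_idx += 1
                    quadrat_id = f"{station_id}Q{q_idx:02d}"
                    sown = seeds_for_level(m, sp.ambient_seed_rain,
                                           design.quadrat_area)
                    S = sown + ambient
                    mu = np.exp(u_plot[p]) * truth.P0 * S / (
                        1.0 + truth.P0 * S / truth.Rmax
                    )
                    if mu > 0:
                        # NB2 via Poisson-gamma mixture
                        lam = rng.gamma(truth.k, mu / truth.k)
                        count = int(rng.poisson(lam))
                    else:
                        count = 0
                    for t, month in enumerate(design.census_months):
                        if t > 0 and count > 0:
                            pr = float(_survival_prob(np.float64(count), truth))
                            count = int(rng.binomial(count, pr))
                        rows["plot_id"].append(plot_id)
                        rows["station_id"].append(station_id)
                        rows["quadrat_id"].append(quadrat_id)
                        rows["species_code"].append(sp.code)
                        rows["aug_multiple"].append(float(m))
                        rows["seeds_added"].append(sown)
                        rows["ambient_seed_rain"].append(sp.ambient_seed_rain)
                        rows["conspecific_density"].append(float(dens[p, j]))
                        rows["census_month"].append(int(month))
                        rows["seedling_count"].append(count)

    return pd.DataFrame(rows, columns=DATASET_COLUMNS)
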