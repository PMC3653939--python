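"""Fundamental limitation decomposition and crossover analysis.

Given fitted Beverton-Holt parameters, the shortfall of recruitment
under ambient conditions relative to recruitment with one limiting
process removed defines four limitation strengths at seed input S
(R = P0*S/(1 + P0*S/Rmax) is ambient recruitment):

    L_S  = Rmax - R                 seed limitation (limitless seed supply,
                                    no mortality)
    L_DI = S/(1 + S/Rmax) - R       density-independent loss (set P0 = 1)
    L_DD = P0*S - R                 density-dependent loss (Rmax -> inf)
    L_E  = S - R                    establishment limitation (both removed:
                                    every seed recruits)

Seed limitation dominates establishment limitation below S* = Rmax and
density-independent losses dominate density-dependent ones below
S* = Rmax*(1 - P0)/P0; both crossovers have closed forms that the
numeric root-finders are checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .recruitment import BHParams, bh_mean

__all__ = [
    "LimitationCurve",
    "TrendResult",
    "limitation_at",
    "crossover_seed_establishment",
    "crossover_dd_di",
    "limitation_curve",
    "temporal_trend",
    "effect_time_slope",
]


class DecompositionUndefinedError(ValueError):
    """Raised when Rmax is infinite: there is no saturation to remove."""


def _check_finite(params: BHParams) -> None:
    if math.isinf(params.Rmax):
        raise DecompositionUndefinedError(
            "limitation decomposition requires finite Rmax"
        )


def limitation_at(S, params: BHParams):
    """Evaluate (L_S, L_DI, L_DD, L_E) at seed input ``S`` (scalar/array)."""
    _check_finite(params)
    S = np.asarray(S, dtype=float)
    R = bh_mean(S, params.P0, params.Rmax)
    L_S = params.Rmax - R
    L_DI = S / (1.0 + S / params.Rmax) - R
    L_DD = params.P0 * S - R
    L_E = S - R
    if S.ndim == 0:
        return float(L_S), float(L_DI), float(L_DD), float(L_E)
    return L_S, L_DI, L_DD, L_E


def crossover_seed_establishment(
    params: BHParams, numeric: bool = False
) -> float:
    """Seed input where establishment limitation overtakes seed limitation.

    L_E - L_S = S - Rmax, so the crossover is S* = Rmax exactly; with
    ``numeric=True`` the root is located by bracketing instead and agrees
    with the closed form to 1e-6 relative.
    """
    _check_finite(params)
    if not numeric:
        return params.Rmax

    def f(S):
        L_S, _, _, L_E = limitation_at(S, params)
        return L_E - L_S

    hi = 2.0 * params.Rmax + 1.0
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12))


def crossover_dd_di(params: BHParams, numeric: bool = False) -> float:
    """Seed input where density-dependent losses overtake density-independent.

    Closed form S* = Rmax*(1 - P0)/P0; at P0 = 1 there is no
    density-independent loss and the crossover degenerates to 0.
    """
    _check_finite(params)
    if params.P0 >= 1.0:
        return 0.0
    closed = params.Rmax * (1.0 - params.P0) / params.P0
    if not numeric:
        return closed

    def f(S):
        _, L_DI, L_DD, _ = limitation_at(S, params)
        return L_DD - L_DI

    return float(optimize.brentq(f, 1e-12, 4.0 * closed + 1.0,
                                 xtol=1e-12, rtol=1e-12))


@dataclass
class LimitationCurve:
    """Limitation strengths on a seed-input grid plus crossover points."""

    seed_grid: np.ndarray
    L_S: np.ndarray
    L_DI: np.ndarray
    L_DD: np.ndarray
    L_E: np.ndarray
    crossover_seed_establishment: float
    crossover_dd_di: float
    ambient_multiple_scale: float  # multiple = S / ambient; nan if no ambient

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "S": self.seed_grid,
            "L_S": self.L_S,
            "L_DI": self.L_DI,
            "L_DD": self.L_DD,
            "L_E": self.L_E,
        })
        if np.isfinite(self.ambient_multiple_scale):
            df["ambient_multiple"] = self.seed_grid / self.ambient_multiple_scale
        return df

    def crossovers_dict(self) -> dict:
        d = {
            "seed_vs_establishment_S": self.crossover_seed_establishment,
            "dd_vs_di_S": self.crossover_dd_di,
        }
        if np.isfinite(self.ambient_multiple_scale) \
                and self.ambient_multiple_scale > 0:
            d["seed_vs_establishment_multiple"] = (
                self.crossover_seed_establishment / self.ambient_multiple_scale
            )
            d["dd_vs_di_multiple"] = (
                self.crossover_dd_di / self.ambient_multiple_scale
            )
        return d


def limitation_curve(
    params: BHParams,
    grid: np.ndarray | None = None,
    ambient: float | None = None,
    grid_max_multiple: float = 2000.0,
    n_points: int = 200,
) -> LimitationCurve:
    """Evaluate the four limitation strengths over a seed-input grid.

    The default grid is log-spaced from a small positive input up to
    ``grid_max_multiple`` ambient multiples (or up to that many seeds if
    no ambient density is available).  Crossovers are attached in both
    seeds-per-quadrat and ambient multiples.
    """
    _check_finite(params)
    if ambient is None:
        ambient = params.S_amb
    scale = float(ambient) if ambient and ambient > 0 else float("nan")
    if ambient is not None and ambient <= 0:
        import warnings
        warnings.warn("ambient seed input <= 0; multiple conversion omitted",
                      stacklevel=2)
    if grid is None:
        unit = scale if np.isfinite(scale) else 1.0
        grid = np.geomspace(unit * 1e-2, unit * grid_max_multiple, n_points)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    L_S, L_DI, L_DD, L_E = limitation_at(grid, params)
    return LimitationCurve(
        seed_grid=grid, L_S=L_S, L_DI=L_DI, L_DD=L_DD, L_E=L_E,
        crossover_seed_establishment=crossover_seed_establishment(params),
        crossover_dd_di=crossover_dd_di(params),
        ambient_multiple_scale=scale,
    )


@dataclass
class TrendResult:
    """Pearson trend of a per-census quantity against census month."""

    quantity: str
    census_months: np.ndarray
    values: np.ndarray
    pearson_r: float
    t_stat: float
    df: int
    p_value: float
    undefined: bool = False


def temporal_trend(
    values, census_months, quantity: str = "quantity"
) -> TrendResult:
    """Pearson correlation of a scalar series against census month.

    Two-sided t test on df = n - 2; a zero-variance series leaves r
    undefined and sets the ``undefined`` flag rather than failing.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(census_months, dtype=float)
    if len(values) != len(months) or len(values) < 3:
        raise ValueError("need >= 3 paired censuses")
    if np.std(values) == 0 or np.std(months) == 0:
        return TrendResult(quantity, months, values, float("nan"),
                           float("nan"), len(values) - 2, float("nan"),
                           undefined=True)
    r, p = stats.pearsonr(values, months)
    df = len(values) - 2
    denom = max(1.0 - r * r, 1e-300)
    t = r * math.sqrt(df / denom)
    return TrendResult(quantity, months, values, float(r), float(t), df,
                       float(p))


def effect_time_slope(effects: pd.DataFrame) -> dict:
    """Pooled linear time trend of effect sizes across species.

    Fits an ordinary least-squares slope of E on census month within each
    species, then pools the per-species slopes by inverse-variance
    weighting (a two-stage stand-in for a random-intercept mixed model).
    Returns the pooled slope with its t statistic and df.  A single
    species falls back to plain OLS, noted in the result.
    """
    if effects.empty:
        raise ValueError("no effect-size records")
    groups = list(effects.groupby("species_code"))
    months_all = effects["census_month"].unique()
    if len(months_all) < 2:
        raise ValueError("need >= 2 censuses for a time slope")

    slopes, variances = [], []
    for _, g in groups:
        if g["census_month"].nunique() < 2:
            continue
        x = g["census_month"].to_numpy(float)
        y = g["E"].to_numpy(float)
        res = stats.linregress(x, y)
        slopes.append(res.slope)
        # perfect fits have zero stderr; give them a tiny variance so the
        # precision weighting stays finite and exact-linear data pools to
        # the common slope
        variances.append(max(res.stderr ** 2, 1e-20)
                         if np.isfinite(res.stderr) else 1e-20)

    fallback = len(slopes) < 2
    if fallback:
        x = effects["census_month"].to_numpy(float)
        y = effects["E"].to_numpy(float)
        res = stats.linregress(x, y)
        df = len(x) - 2
        t = res.slope / res.stderr if res.stderr > 0 else float("inf")
        return {"slope": float(res.slope), "t_stat": float(t), "df": df,
                "method": "ols_fallback"}

    w = 1.0 / np.asarray(variances)
    slope = float(np.sum(w * np.asarray(slopes)) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    df = len(slopes) - 1
    t = slope / se if se > 0 else float("inf")
    return {"slope": slope, "t_stat": float(t), "df": df,
            "method": "two_stage_pooled"}
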