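"""Realized limitation via the per-seed recruitment effect size.

The effect size for one augmentation level is the number of new recruits
per seed added,

    E = (N_treatment - N_control) / seeds_added,

where N_control normalizes for background seed arrival and establishment.
E near 1 indicates strong seed limitation (every added seed recruits);
E near 0 indicates strong establishment limitation.  E can fall outside
[0, 1] by chance or under strong density dependence; such values are kept
and flagged, never clipped, since clipping would bias plot-level means.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "quadrat_effect_size",
    "plot_effect_sizes",
    "effect_size_time_series",
    "EFFECT_COLUMNS",
]

log = logging.getLogger(__name__)

EFFECT_COLUMNS = [
    "plot_id",
    "species_code",
    "aug_multiple",
    "census_month",
    "E",
    "n_quadrats",
    "flagged",
]


class UndefinedEffectError(ValueError):
    """The control level (0 seeds added) has no per-seed effect size."""


def quadrat_effect_size(
    treatment_count: float, control_count: float, seeds_added: int
) -> float:
    """Per-seed recruitment effect size for a single treatment quadrat."""
    if seeds_added == 0:
        raise UndefinedEffectError(
            "effect size is undefined when no seeds were added"
        )
    if seeds_added < 0:
        raise ValueError("seeds_added must be >= 0")
    return (treatment_count - control_count) / seeds_added


def plot_effect_sizes(
    records: pd.DataFrame, census_month: int
) -> pd.DataFrame:
    """Plot-level effect sizes for every species x augmentation level.

    For each plot x species the control reference is the mean seedling
    count over that plot's control (``aug_multiple == 0``) quadrats at the
    requested census.  Each treatment quadrat yields
    ``(count - control_mean) / seeds_added`` and quadrats sharing a
    plot x species x level are averaged into one record.

    Strata without any control quadrat are skipped with a warning listing
    the offending (plot, species) pairs.  Effect sizes outside [0, 1] are
    flagged via the ``flagged`` column.
    """
    sub = records[records["census_month"] == census_month]
    out: dict[str, list] = {c: [] for c in EFFECT_COLUMNS}
    skipped: list[tuple[str, str]] = []

    for (plot, sp), grp in sub.groupby(["plot_id", "species_code"], sort=True):
        controls = grp[grp["aug_multiple"] == 0]
        if controls.empty:
            skipped.append((plot, sp))
            continue
        control_mean = controls["seedling_count"].mean()
        treat = grp[(grp["aug_multiple"] > 0) & (grp["seeds_added"] > 0)]
        for level, lg in treat.groupby("aug_multiple", sort=True):
            e_vals = (lg["seedling_count"] - control_mean) / lg["seeds_added"]
            e = float(e_vals.mean())
            out["plot_id"].append(plot)
            out["species_code"].append(sp)
            out["aug_multiple"].append(float(level))
            out["census_month"].append(int(census_month))
            out["E"].append(e)
            out["n_quadrats"].append(int(len(lg)))
            out["flagged"].append(bool(e < 0 or e > 1))

    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} strata without control quadrats at "
            f"census {census_month}: {skipped[:10]}",
            stacklevel=2,
        )
    return pd.DataFrame(out, columns=EFFECT_COLUMNS)


def effect_size_time_series(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`plot_effect_sizes` at every census, sorted by census."""
    if records.empty:
        return pd.DataFrame(columns=EFFECT_COLUMNS)
    months = sorted(records["census_month"].unique())
    parts = [plot_effect_sizes(records, m) for m in months]
    return pd.concat(parts, ignore_index=True)
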