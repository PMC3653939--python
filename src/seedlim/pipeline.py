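"""End-to-end pipeline: simulate -> effects -> (glmm) -> fit -> decompose
-> trends, with a machine-readable manifest of every artifact."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects as eff
from . import glmm as hg
from . import io as sio
from . import limitation as lim
from . import recruitment as rec
from .synthetic import simulate_experiment

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: sio.PipelineConfig) -> dict:
    """Run every configured stage and return the output manifest.

    Artifacts (CSV/JSON) land in ``config.out_dir``; the manifest lists
    each with its SHA-256 checksum plus the config hash and stage
    timings, and is itself written as ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = sio.config_hash(config)
    manifest: dict = {"config_hash": chash, "rng_seed": config.rng_seed,
                      "artifacts": {}, "timings_s": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": sio.file_checksum(path),
        }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name,
                     manifest["timings_s"][name])
            return result
        return wrap

    # --- data -------------------------------------------------------------
    if config.simulate:
        @stage("simulate")
        def records():
            df = simulate_experiment(config.design, config.truth,
                                     config.rng_seed)
            record("dataset", sio.write_dataset(df, out / "dataset.csv"))
            return df
    else:
        @stage("load")
        def records():
            return sio.read_dataset(config.dataset)

    censuses = (list(config.censuses) if config.censuses
                else sorted(records["census_month"].unique()))

    # --- realized limitation ----------------------------------------------
    @stage("effects")
    def effects_df():
        df = eff.effect_size_time_series(records)
        path = out / "effect_sizes.csv"
        df.to_csv(path, index=False)
        record("effect_sizes", path)
        return df

    if config.run_glmm:
        @stage("glmm")
        def _():
            opts = hg.McmcOptions(chains=config.mcmc_chains,
                                  burn_in=config.mcmc_burn_in,
                                  draws=config.mcmc_draws)
            summ = hg.fit_effect_glmm(
                records, censuses[0], chains=config.mcmc_chains,
                burn_in=config.mcmc_burn_in, draws=config.mcmc_draws,
                rng_seed=config.rng_seed, options=opts,
            )
            path = out / "glmm_effect_posterior.csv"
            summ.to_csv(path, index=False)
            record("glmm_effect_posterior", path)
            draws = summ.attrs["draws"]
            n_chains, n_draws, n_par = draws.shape
            flat = pd.DataFrame(draws.reshape(-1, n_par),
                                columns=summ.attrs["names"])
            flat.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
            dpath = out / "glmm_effect_draws.csv"
            flat.to_csv(dpath, index=False)
            record("glmm_effect_draws", dpath)

    # --- fundamental limitation --------------------------------------------
    @stage("fit")
    def fits():
        opts = rec.FitOptions(n_nodes=config.n_nodes,
                              n_starts=config.n_starts)
        results = {}
        rows = []
        for month in censuses:
            month_fits = []
            for model in config.models:
                fr = rec.fit_model(records, month, model, opts,
                                   quadrat_area=config.design.quadrat_area,
                                   ambient_window_years=config.design
                                   .ambient_window_years)
                month_fits.append(fr)
                d = fr.to_dict()
                rows.append({"census_month": month, "model": fr.model.value,
                             **d["estimates"], "loglik": fr.loglik,
                             "aic": fr.aic, "converged": fr.converged})
            results[month] = month_fits
        path = out / "fits.json"
        path.write_text(json.dumps(
            {str(m): [f.to_dict() for f in fs] for m, fs in results.items()},
            indent=2, sort_keys=True, default=_json_default))
        record("fits", path)
        cpath = out / "fit_estimates.csv"
        pd.DataFrame(rows).to_csv(cpath, index=False)
        record("fit_estimates", cpath)
        return results

    @stage("decompose")
    def curves():
        by_census = {}
        for month, month_fits in fits.items():
            dd = next((f for f in month_fits if f.model is rec.Model.DD), None)
            if dd is None:
                continue
            curve = lim.limitation_curve(dd.estimates)
            by_census[month] = curve
            curve.to_frame().to_csv(out / f"limitation_{month:02d}.csv",
                                    index=False)
            record(f"limitation_{month:02d}",
                   out / f"limitation_{month:02d}.csv")
        path = out / "crossovers.json"
        path.write_text(json.dumps(
            {str(m): c.crossovers_dict() for m, c in by_census.items()},
            indent=2, sort_keys=True, default=_json_default))
        record("crossovers", path)
        return by_census

    @stage("trends")
    def _():
        trends = {}
        months = sorted(curves)
        if len(months) >= 3:
            amb = {m: curves[m].ambient_multiple_scale for m in months}
            for name, getter in [
                ("L_S", lambda c, a: float(np.interp(a, c.seed_grid, c.L_S))),
                ("L_DI", lambda c, a: float(np.interp(a, c.seed_grid, c.L_DI))),
                ("L_DD", lambda c, a: float(np.interp(a, c.seed_grid, c.L_DD))),
                ("L_E", lambda c, a: float(np.interp(a, c.seed_grid, c.L_E))),
            ]:
                # limitation strength at ambient seed input, per census
                vals = [getter(curves[m], amb[m]) for m in months]
                tr = lim.temporal_trend(vals, months, quantity=name)
                trends[name] = {
                    "values": list(tr.values), "r": tr.pearson_r,
                    "t": tr.t_stat, "df": tr.df, "p": tr.p_value,
                    "undefined": tr.undefined,
                }
        if not effects_df.empty and \
                effects_df["census_month"].nunique() >= 2:
            trends["effect_size_slope"] = lim.effect_time_slope(effects_df)
        path = out / "trends.json"
        path.write_text(json.dumps(trends, indent=2, sort_keys=True,
                                   default=_json_default))
        record("trends", path)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
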