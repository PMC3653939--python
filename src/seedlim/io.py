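"""Dataset schema enforcement, configuration and output helpers."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    DATASET_COLUMNS,
    ExperimentDesign,
    SpeciesProfile,
    TrueParams,
)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_dataset",
    "write_dataset",
    "load_config",
    "config_hash",
    "file_checksum",
]


class SchemaError(ValueError):
    """The CSV does not conform to the per-quadrat census schema."""


_NUMERIC = {
    "aug_multiple": float,
    "seeds_added": int,
    "ambient_seed_rain": float,
    "conspecific_density": float,
    "census_month": int,
    "seedling_count": int,
}


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-quadrat census CSV.

    Columns are matched by name (any order).  Validation enforces the
    record invariants: non-negative counts and seed numbers, controls
    with zero seeds added, and per-quadrat seedling counts that never
    increase between censuses.  Violations are reported with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[DATASET_COLUMNS].copy()
    for col, typ in _NUMERIC.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            rows = df.index[bad].tolist()[:10]
            raise SchemaError(
                f"column {col!r} has unparseable values at rows {rows}"
            ) from exc
    _validate_records(df)
    return df


def _validate_records(df: pd.DataFrame) -> None:
    problems: list[str] = []
    for col in ("seedling_count", "seeds_added", "aug_multiple"):
        bad = df.index[df[col] < 0]
        if len(bad):
            problems.append(f"{col} < 0 at rows {bad.tolist()[:10]}")
    bad = df.index[(df["aug_multiple"] == 0) & (df["seeds_added"] != 0)]
    if len(bad):
        problems.append(
            f"control quadrats with seeds_added != 0 at rows {bad.tolist()[:10]}"
        )
    # counts must be non-increasing through the censuses of each quadrat
    srt = df.sort_values(["quadrat_id", "census_month"], kind="stable")
    same = srt["quadrat_id"].to_numpy()[1:] == srt["quadrat_id"].to_numpy()[:-1]
    rising = srt["seedling_count"].to_numpy()[1:] > \
        srt["seedling_count"].to_numpy()[:-1]
    bad = srt.index[1:][same & rising]
    if len(bad):
        problems.append(
            f"seedling_count increases over time at rows {bad.tolist()[:10]}"
        )
    if problems:
        raise SchemaError("; ".join(problems))


def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[DATASET_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    design: ExperimentDesign = dataclasses.field(
        default_factory=ExperimentDesign)
    truth: TrueParams = dataclasses.field(default_factory=TrueParams)
    rng_seed: int | None = None
    out_dir: str = "results"
    simulate: bool = True
    dataset: str | None = None  # read instead of simulating
    censuses: tuple[int, ...] | None = None  # None = all in the data
    models: tuple[str, ...] = ("DD", "DI")
    n_nodes: int = 20
    n_starts: int = 5
    run_glmm: bool = False
    mcmc_chains: int = 3
    mcmc_burn_in: int = 1000
    mcmc_draws: int = 1000

    def validate(self) -> None:
        if self.simulate and self.rng_seed is None:
            raise ValueError("rng_seed is mandatory when simulation is enabled")
        if self.run_glmm and self.rng_seed is None:
            raise ValueError("rng_seed is mandatory when the MCMC stage runs")
        if not self.simulate and not self.dataset:
            raise ValueError("either enable simulate or provide a dataset path")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    design_raw = raw.pop("design", {})
    species_raw = design_raw.pop("species", None)
    if species_raw is not None:
        design_raw["species"] = tuple(
            SpeciesProfile(**sp) for sp in species_raw
        )
    for key in ("aug_multiples", "census_months"):
        if key in design_raw:
            design_raw[key] = tuple(design_raw[key])
    truth_raw = raw.pop("truth", {})
    for key in ("censuses", "models"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(
        design=ExperimentDesign(**design_raw),
        truth=TrueParams(**truth_raw),
        **raw,
    )
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
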