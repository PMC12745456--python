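"""Dataset and configuration I/O.

Datasets follow NONMEM column semantics in plain CSV: one row per dose event
(``EVID=1``) or observation (``EVID=0``), identified by ``ID`` and ordered by
``TIME`` (hours) within each individual.  Required columns are ID, TIME,
EVID, AMT, DUR, DV, MDV, WT; the optional columns carry covariates and flags
(AGE, BSE, SCRN, STUDYGRP, JPN, BLQ).  Validation is strict and names the
offending column or individuals, never silently repairs.

Run configuration is a single pydantic-validated structure (unknown keys
rejected) holding the fixed effects, IIV and residual blocks, the cohort
specification and the seeds; :func:`run_metadata` hashes it so that any
output can be reproduced from (config, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import DatasetSchemaError

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "WT")
OPTIONAL_COLUMNS = ("AGE", "BSE", "SCRN", "STUDYGRP", "JPN", "BLQ")


@dataclass(frozen=True)
class Dataset:
    """A validated long-format dosing/observation table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_dataset(self.df)

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False)
        return path


def validate_dataset(df: pd.DataFrame) -> None:
    """Raise :class:`DatasetSchemaError` describing the first schema violation."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DatasetSchemaError(f"missing required column: {col}")
    if np.any(df["TIME"].to_numpy() < 0.0):
        raise DatasetSchemaError("TIME must be >= 0 for all records")
    bad_sort = [
        int(i)
        for i, g in df.groupby("ID", sort=False)
        if not g["TIME"].is_monotonic_increasing
    ]
    if bad_sort:
        raise DatasetSchemaError(
            f"times are not sorted within individuals: IDs {bad_sort}"
        )
    dose_rows = df[df["EVID"] == 1]
    bad_dv = dose_rows[(dose_rows["MDV"] == 0) & dose_rows["DV"].notna()]
    if len(bad_dv):
        raise DatasetSchemaError(
            "dose rows (EVID=1) must not carry observations "
            f"(MDV=0 with DV set): IDs {sorted(bad_dv['ID'].unique().tolist())}"
        )
    obs = df[df["EVID"] == 0]
    if obs["DV"].isna().all() and len(obs):
        raise DatasetSchemaError("observation rows carry no DV values")


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a CSV dataset (bit-exact float round trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return Dataset(df)


def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    """Validate and write a dataframe as a CSV dataset."""
    return Dataset(df).write(path)


# ---------------------------------------------------------------------------
# summary-table writers
# ---------------------------------------------------------------------------

TableStyle = Literal["table3", "table4", "table5", "table7"]

_GROUP_ORDER = ("0-<6", "6-<12", "12-<18", ">=12", ">=18")


def write_summary_tables(
    summary: pd.DataFrame, style: TableStyle, path: str | Path
) -> Path:
    """Write a tidy regimen-summary frame as an age-stratified wide CSV table.

    ``table3`` pivots single-dose durations (rows: dose x threshold, cells:
    median and 25th percentile in days, half-day resolution); ``table4``
    steady-state troughs (median and 90% PI, one decimal); ``table5``
    attainment percentages (one decimal); ``table7`` exposure metrics by
    population.  Cells with no summary stay empty rather than being invented.
    """
    path = Path(path)
    if style == "table3":
        wide = summary.pivot_table(
            index=["dose_iu_kg", "threshold_iu_dl"],
            columns="age_group",
            values=["median_days", "p25_days"],
        )
    elif style == "table4":
        wide = summary.pivot_table(
            index=["dose_iu_kg", "interval_days"],
            columns="age_group",
            values=["median_iu_dl", "p5_iu_dl", "p95_iu_dl"],
        ).round(1)
    elif style == "table5":
        wide = summary.pivot_table(
            index=["dose_iu_kg", "interval_days", "cutoff_iu_dl"],
            columns="age_group",
            values="pct_above",
        ).round(1)
    elif style == "table7":
        wide = summary.pivot_table(
            index="metric", columns="population", values=["median", "p5", "p95"]
        ).round(1)
    else:
        raise ValueError(f"unknown table style: {style}")
    if isinstance(wide.columns, pd.MultiIndex):
        order = [g for g in _GROUP_ORDER if g in wide.columns.get_level_values(-1)]
        if order:
            wide = wide.reindex(columns=order, level=-1)
        wide.columns = ["_".join(map(str, c)) for c in wide.columns]
    else:
        order = [g for g in _GROUP_ORDER if g in wide.columns]
        if order:
            wide = wide[order]
    wide.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class FixedEffectsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_activity: float = 0.992
    cl_70: float = 0.550
    vc_ref: float = 65.7
    q: float = 0.208
    vp_70: float = 19.5
    exp_wt_cl: float = 0.528
    exp_wt_v: float = 0.771
    exp_dose_vc: float = 0.281


class IIVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    omega2_cl: float = 0.0386
    omega2_vc: float = 0.0562
    omega2_base: float = 0.176


class ResidualConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prop_sd_group1: float = 0.181
    add_sd_group1: float = 0.683
    prop_sd_group2: float = 0.371
    add_sd_group2: float = 1.20


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"0-<6": 12, "6-<12": 15, "12-<18": 5, ">=18": 81}
    )
    per_kg_cl_medians: dict[str, float] = Field(
        default_factory=lambda: {
            "0-<6": 0.0155,
            "6-<12": 0.0114,
            "12-<18": 0.0103,
            ">=18": 0.00822,
        }
    )
    weight_gcv: float = 0.20


class RegimenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dose_per_kg: float
    interval_days: float | None = None
    infusion_duration_h: float = 1.0 / 6.0


class RunConfig(BaseModel):
    """Validated configuration of a fixsim run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    fixed_effects: FixedEffectsConfig = Field(default_factory=FixedEffectsConfig)
    iiv: IIVConfig = Field(default_factory=IIVConfig)
    residual: ResidualConfig = Field(default_factory=ResidualConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    regimens: list[RegimenConfig] = Field(default_factory=list)
    seed: int = 0
    n_replicates: int = 1000

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=2))
        return path

    def fixed_effects_obj(self):
        from .covariates import FixedEffects

        return FixedEffects(**self.fixed_effects.model_dump())

    def iiv_obj(self):
        from .population import IIVParameters

        return IIVParameters(**self.iiv.model_dump())

    def residual_obj(self):
        from .population import ResidualError

        return ResidualError(**self.residual.model_dump())


def run_metadata(config: RunConfig) -> dict:
    """Reproducibility record: config hash, seed and package version."""
    from . import __version__

    payload = config.model_dump_json().encode()
    return {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": config.seed,
        "fixsim_version": __version__,
    }
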