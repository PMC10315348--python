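"""Plain-text readers and writers: series CSV, profile CSV, fits JSON/CSV,
and YAML run configuration.

The series CSV dialect is ``day, replicate, phase, concentration_ug_ml``
(header required, UTF-8, decimal point).  All outputs are lossless text so
an entire run can live under version control.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .accounting import (
    ConcentrationSeries,
    ReleaseProfile,
    SamplingProtocol,
    biphasic_protocol,
    daily_protocol,
    monophasic_protocol,
)
from .assessment import MediumSpec
from .errors import EmptyInputError, ValidationError
from .physchem import DrugProperties
from .release_models import ModelFit

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_fits_json",
    "write_fits_csv",
    "load_config",
    "drug_from_dict",
    "medium_from_dict",
    "protocol_from_dict",
]

SERIES_COLUMNS = ["day", "replicate", "phase", "concentration_ug_ml"]


def read_series_csv(path) -> list[ConcentrationSeries]:
    """Read measured concentration series, one per (replicate, phase).

    Rows may arrive in any order; each series is sorted by day.  Negative
    concentrations and missing columns are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {SERIES_COLUMNS}"
        )
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if (df["concentration_ug_ml"] < 0).any():
        bad = df.index[df["concentration_ug_ml"] < 0][0]
        raise ValidationError(
            f"{path}: negative concentration at data row {bad + 1}"
        )
    out = []
    for (rep, phase), grp in df.groupby(["replicate", "phase"], sort=False):
        out.append(
            ConcentrationSeries(
                replicate_id=str(rep),
                phase=str(phase),
                times=grp["day"].to_numpy(dtype=float),
                concentrations=grp["concentration_ug_ml"].to_numpy(dtype=float),
            )
        )
    return out


def write_series_csv(series: Sequence[ConcentrationSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "day": s.times,
                "replicate": s.replicate_id,
                "phase": s.phase,
                "concentration_ug_ml": s.concentrations,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_profiles_csv(profiles: Sequence[ReleaseProfile], path) -> None:
    frames = []
    for p in profiles:
        d = {
            "replicate": p.replicate_id,
            "day": p.times,
            "interval_ug": p.interval_amounts,
            "cumulative_ug": p.cumulative,
            "interval_days": p.interval_lengths,
            "daily_rate_ug_day": p.daily_rates,
        }
        if p.fractional is not None:
            d["fraction_released"] = p.fractional
        if p.cumulative_sd is not None:
            d["cumulative_sd_ug"] = p.cumulative_sd
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path) -> list[ReleaseProfile]:
    df = pd.read_csv(path)
    required = {"replicate", "day", "interval_ug", "cumulative_ug", "interval_days"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("day")
        out.append(
            ReleaseProfile(
                replicate_id=str(rep),
                times=grp["day"].to_numpy(dtype=float),
                interval_amounts=grp["interval_ug"].to_numpy(dtype=float),
                cumulative=grp["cumulative_ug"].to_numpy(dtype=float),
                interval_lengths=grp["interval_days"].to_numpy(dtype=float),
                fractional=(
                    grp["fraction_released"].to_numpy(dtype=float)
                    if "fraction_released" in grp
                    else None
                ),
            )
        )
    return out


def _fit_record(label: str, fit: ModelFit) -> dict:
    return {
        "medium": label,
        "model": fit.model,
        "slope": fit.slope,
        "slope_ci_lo": fit.ci95_slope[0],
        "slope_ci_hi": fit.ci95_slope[1],
        "intercept": fit.intercept,
        "intercept_ci_lo": fit.ci95_intercept[0],
        "intercept_ci_hi": fit.ci95_intercept[1],
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "fit_window": list(fit.fit_window),
    }


def write_fits_json(fits: dict[str, ModelFit], path) -> None:
    records = [_fit_record(label, f) for label, f in fits.items()]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def write_fits_csv(
    rows: Sequence[dict],
    path,
) -> None:
    """Summary table, one row per medium: day-28 cumulative release (mg),
    rate-equation slope/intercept with CIs, R^2 and Peppas parameters."""
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- config ---

def drug_from_dict(d: dict) -> DrugProperties:
    return DrugProperties(
        name=d.get("name", ""),
        molecular_weight=float(d["molecular_weight"]),
        pKa=float(d["pKa"]),
        logP=float(d["logP"]),
        intrinsic_solubility=float(d["intrinsic_solubility"]),
        ring_loading=float(d["ring_loading"]),
        medium_solubilities={
            str(k): float(v) for k, v in d.get("medium_solubilities", {}).items()
        },
    )


def medium_from_dict(d: dict) -> MediumSpec:
    return MediumSpec(
        label=str(d["label"]),
        solubility=float(d["solubility"]),
        volume=float(d.get("volume", 100.0)),
        cosolvent_percent=float(d.get("cosolvent_percent", 0.0)),
        pH=float(d["pH"]) if d.get("pH") is not None else None,
    )


def protocol_from_dict(d: dict) -> SamplingProtocol:
    kind = d.get("kind", "monophasic")
    days = int(d.get("days", 28))
    if kind == "monophasic":
        if d.get("skip_weekends", True):
            return monophasic_protocol(
                days,
                volume=float(d.get("volume_ml", 100.0)),
                weekend_volume=float(d.get("weekend_volume_ml", 200.0)),
                initial_volume=float(d.get("initial_volume_ml", 200.0)),
            )
        return daily_protocol(days, volume=float(d.get("volume_ml", 100.0)))
    if kind == "biphasic":
        return biphasic_protocol(
            days,
            buffer_volume=float(d.get("volume_ml", 100.0)),
            octanol_volume=float(d.get("octanol_volume_ml", 20.0)),
            sample_volume=float(d.get("sample_ml", 1.0)),
            octanol_dilution=float(d.get("dilution_factor", 20.0)),
        )
    raise ValidationError(f"unknown protocol kind {kind!r}")


def load_config(path) -> dict:
    """Load a YAML run configuration; returns the raw mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
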