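"""End-to-end glue: files -> trajectories -> summaries -> analysis table -> models."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import arena as arena_mod
from . import mixedstats, tracks, water
from .arena import ArenaSpec, HumidityField

__all__ = [
    "build_analysis_table",
    "process_study",
    "analyze_study",
    "cohort_summary",
]


def build_analysis_table(summaries: pd.DataFrame, water_records: pd.DataFrame) -> pd.DataFrame:
    """Join behavioural summaries with water-balance records into the model table.

    One row per animal x temperature with the columns the mixed models use:
    ``animal_id``, ``temperature``, ``median_vpd``, ``median_rh``, ``log_mb``,
    ``log_ewl``, ``log_rer``, ``total_distance_m``.  Log transforms are
    natural logs; non-positive rates yield NaN (excluded downstream by the
    fitting routine's caller).
    """
    s = summaries.rename(
        columns={
            "test_temperature_C": "temperature",
            "median_selected_vpd_kPa": "median_vpd",
            "median_selected_rh_pct": "median_rh",
        }
    )
    w = water_records.rename(columns={"test_temperature_C": "temperature"})
    merged = s.merge(
        w[["animal_id", "temperature", "mass_pre_g", "ewl_ml_per_h", "rer_ml_per_h"]],
        on=["animal_id", "temperature"],
        how="inner",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["log_mb"] = np.log(merged["mass_pre_g"])
        merged["log_ewl"] = np.where(
            merged["ewl_ml_per_h"] > 0, np.log(merged["ewl_ml_per_h"].clip(lower=1e-300)), np.nan
        )
        merged["log_rer"] = np.where(
            merged["rer_ml_per_h"] > 0, np.log(merged["rer_ml_per_h"].clip(lower=1e-300)), np.nan
        )
    cols = [
        "animal_id",
        "sex",
        "temperature",
        "median_vpd",
        "median_rh",
        "log_mb",
        "log_ewl",
        "log_rer",
        "total_distance_m",
    ]
    return merged[[c for c in cols if c in merged.columns]]


def process_study(
    manifest_path,
    fields: dict[float, HumidityField],
    mass_csv_path,
    arena: ArenaSpec | None = None,
    trial_duration_h: float = water.DEFAULT_TRIAL_DURATION_H,
) -> dict:
    """Run the full ingest pipeline over a trial manifest.

    The manifest CSV binds each tracking file to its animal id, sex, test
    temperature and lane (an optional ``frame_interval_s`` column overrides
    the arena's default imaging interval).  Every trial is read, split into
    habituation and experimental periods, and the experimental period reduced
    against the calibration field for its temperature; the mass CSV supplies
    EWL/ReR.  Returns summaries, water records and the joined analysis table.
    """
    arena = arena or ArenaSpec()
    manifest = pd.read_csv(manifest_path)
    base = Path(manifest_path).parent
    summaries = []
    for row in manifest.itertuples(index=False):
        meta = tracks.TrialMeta(
            animal_id=str(row.animal_id),
            sex=str(row.sex),
            test_temperature_C=float(row.temperature_c),
            lane=str(row.lane),
        )
        interval = float(getattr(row, "frame_interval_s", arena.frame_interval_s))
        traj = tracks.read_manual_tracking(base / row.file, meta, frame_interval_s=interval)
        _, exp = tracks.split_periods(traj)
        summaries.append(
            tracks.summarize_animal(exp, fields[meta.test_temperature_C], arena)
        )
    summaries_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])

    mass = water.read_mass_csv(mass_csv_path)
    records = [
        water.water_record(
            animal_id=str(r.animal_id),
            test_temperature_C=float(r.test_temperature_C),
            mass_pre_g=float(r.mass_pre_g),
            mass_post_g=float(r.mass_post_g),
            mass_rehydrated_g=float(r.mass_rehydrated_g),
            trial_duration_h=trial_duration_h,
        )
        for r in mass.itertuples(index=False)
    ]
    water_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return {
        "summaries": summaries_df,
        "water_records": water_df,
        "analysis_table": build_analysis_table(summaries_df, water_df),
    }


def analyze_study(table: pd.DataFrame) -> dict[str, mixedstats.ModelFit]:
    """Fit the four preset model families on the joined analysis table.

    Rows with undefined log rates are dropped per model (a model only sees
    complete cases for its own variables).
    """
    fits = {}
    for name, (response, terms, _) in mixedstats.MODEL_PRESETS.items():
        needed = [response] + [t.replace("C(", "").rstrip(")") for t in terms]
        sub = table.dropna(subset=[c for c in needed if c in table.columns])
        fits[name] = mixedstats.fit_preset(sub, name)
    return fits


def cohort_summary(table: pd.DataFrame, water_records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-temperature mean +- SD (min, max) of the headline outcomes."""
    rows = []
    merged = table
    if water_records is not None:
        w = water_records.rename(columns={"test_temperature_C": "temperature"})
        merged = table.merge(
            w[["animal_id", "temperature", "ewl_ml_per_h", "rer_ml_per_h", "mass_pre_g"]],
            on=["animal_id", "temperature"],
            how="left",
        )
    metrics = {
        "median_vpd": "Selected VPD (kPa)",
        "median_rh": "Selected RH (%)",
        "mass_pre_g": "Body mass (g)",
        "ewl_ml_per_h": "EWL (ml/h)",
        "rer_ml_per_h": "ReR (ml/h)",
        "total_distance_m": "Total distance moved (m)",
    }
    for t, grp in merged.groupby("temperature"):
        for col, label in metrics.items():
            if col not in grp.columns:
                continue
            v = grp[col].dropna()
            rows.append(
                {
                    "temperature_C": t,
                    "metric": label,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "min": v.min(),
                    "max": v.max(),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)
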