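"""Water-balance rates and the Van't Hoff temperature coefficient.

Evaporative water loss (EWL) is measured gravimetrically: body mass lost over
a trial divided by its duration, with 1 g of water taken as 1 ml.  The
rehydration rate (ReR) is the mass gained during a standardised 30 min
immersion, scaled to an hourly rate.  The thermal sensitivity of ReR between
the two test temperatures is the Q10 temperature coefficient,
``Q10 = (R2/R1) ** (10 / (T2 - T1))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WaterRecord",
    "WaterBalanceWarning",
    "ewl_rate",
    "rehydration_rate",
    "mass_loss_pct",
    "q10",
    "water_record",
    "cohort_q10",
    "read_mass_csv",
]

WATER_DENSITY_G_PER_ML = 1.0  # implicit in the gravimetric g -> ml conversion

#: Default trial duration used as the EWL denominator: the full 12 h in the
#: gradient.  The 9 h experimental period is a supported alternative.
DEFAULT_TRIAL_DURATION_H = 12.0


class WaterBalanceWarning(UserWarning):
    """Signals physiologically unusual (but not invalid) mass changes."""


@dataclass(frozen=True)
class WaterRecord:
    """Per-trial gravimetric water balance of one animal."""

    animal_id: str
    test_temperature_C: float
    mass_pre_g: float
    mass_post_g: float
    mass_rehydrated_g: float
    trial_duration_h: float
    ewl_ml_per_h: float
    rer_ml_per_h: float
    mass_loss_pct: float


def _check_masses(*masses):
    for m in masses:
        if m <= 0.0:
            raise ValueError(f"body mass must be positive, got {m!r} g")


def ewl_rate(mass_pre_g: float, mass_post_g: float, trial_duration_h: float) -> float:
    """EWL (ml/h): mass lost over the trial divided by its duration.

    A net mass *gain* returns a negative rate with a warning rather than an
    error (condensation or voiding can produce it).
    """
    _check_masses(mass_pre_g, mass_post_g)
    if trial_duration_h <= 0.0:
        raise ValueError(f"trial duration must be positive, got {trial_duration_h!r} h")
    rate = (mass_pre_g - mass_post_g) / WATER_DENSITY_G_PER_ML / trial_duration_h
    if rate < 0.0:
        warnings.warn(
            f"net mass gain during trial ({mass_post_g - mass_pre_g:.3f} g); "
            "EWL is negative",
            WaterBalanceWarning,
            stacklevel=2,
        )
    return rate


def rehydration_rate(mass_post_g: float, mass_after_30min_g: float) -> float:
    """ReR (ml/h): mass gained over the 30 min immersion, scaled x2 to hourly."""
    _check_masses(mass_post_g, mass_after_30min_g)
    rate = (mass_after_30min_g - mass_post_g) / WATER_DENSITY_G_PER_ML * 2.0
    if rate < 0.0:
        warnings.warn(
            "mass loss during rehydration; ReR is negative",
            WaterBalanceWarning,
            stacklevel=2,
        )
    return rate


def mass_loss_pct(mass_pre_g: float, mass_post_g: float) -> float:
    """Percentage of pre-trial body mass lost during the trial."""
    _check_masses(mass_pre_g, mass_post_g)
    return 100.0 * (mass_pre_g - mass_post_g) / mass_pre_g


def q10(rate_at_T1: float, rate_at_T2: float, T1_C: float, T2_C: float) -> float:
    """Van't Hoff Q10: the factor a rate changes per 10 degC rise.

    ``(R2/R1) ** (10/(T2-T1))``; equal rates give 1, and swapping both rates
    and temperatures leaves the value unchanged.
    """
    if rate_at_T1 <= 0.0 or rate_at_T2 <= 0.0:
        raise ValueError("Q10 requires strictly positive rates")
    if T1_C == T2_C:
        raise ValueError("Q10 undefined for equal temperatures")
    return (rate_at_T2 / rate_at_T1) ** (10.0 / (T2_C - T1_C))


def water_record(
    animal_id: str,
    test_temperature_C: float,
    mass_pre_g: float,
    mass_post_g: float,
    mass_rehydrated_g: float,
    trial_duration_h: float = DEFAULT_TRIAL_DURATION_H,
) -> WaterRecord:
    """Build the full per-trial water-balance record from the three weighings."""
    return WaterRecord(
        animal_id=animal_id,
        test_temperature_C=test_temperature_C,
        mass_pre_g=mass_pre_g,
        mass_post_g=mass_post_g,
        mass_rehydrated_g=mass_rehydrated_g,
        trial_duration_h=trial_duration_h,
        ewl_ml_per_h=ewl_rate(mass_pre_g, mass_post_g, trial_duration_h),
        rer_ml_per_h=rehydration_rate(mass_post_g, mass_rehydrated_g),
        mass_loss_pct=mass_loss_pct(mass_pre_g, mass_post_g),
    )


def cohort_q10(
    records: pd.DataFrame, T1_C: float = 17.0, T2_C: float = 22.0
) -> dict:
    """Per-individual Q10 of ReR across the two test temperatures.

    Expects columns ``animal_id``, ``test_temperature_C``, ``rer_ml_per_h``
    with one row per animal x temperature.  Each animal's paired rates give
    one Q10; the cohort is summarised by the arithmetic mean +- SD (the
    conventional report) and by the geometric mean, which is the consistent
    estimator of a shared underlying Q10 under multiplicative trial noise.
    Animals with a non-positive rate at either temperature are dropped.
    """
    wide = records.pivot_table(
        index="animal_id", columns="test_temperature_C", values="rer_ml_per_h"
    )
    if T1_C not in wide.columns or T2_C not in wide.columns:
        raise ValueError(f"records lack both temperatures {T1_C} and {T2_C}")
    wide = wide[(wide[T1_C] > 0) & (wide[T2_C] > 0)].dropna()
    values = np.array(
        [q10(r1, r2, T1_C, T2_C) for r1, r2 in zip(wide[T1_C], wide[T2_C])]
    )
    if values.size == 0:
        raise ValueError("no animal has positive paired rates at both temperatures")
    return {
        "per_individual": pd.Series(values, index=wide.index),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        "geometric_mean": float(math.exp(np.mean(np.log(values)))),
        "n": int(values.size),
    }


def read_mass_csv(path) -> pd.DataFrame:
    """Read the per-trial mass-record CSV
    (`animal_id,sex,temperature_c,mass_pre_g,mass_post_g,mass_rehydrated_g`)."""
    df = pd.read_csv(path)
    required = {
        "animal_id",
        "sex",
        "temperature_c",
        "mass_pre_g",
        "mass_post_g",
        "mass_rehydrated_g",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mass CSV {path} missing columns {sorted(missing)}")
    return df.rename(columns={"temperature_c": "test_temperature_C"})
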