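"""Synthetic humidity-gradient study: a humidistat agent plus water-balance records.

The generator reproduces the study design end to end so the analysis pipeline
can be validated by parameter recovery: 44 animals (22 F / 22 M), each tested
once at 17 and once at 22 degC in a 12 h trial imaged every 30 s (1440
frames), with hygro-logger calibration files, Fiji-style tracking CSVs and a
three-weighing mass record per trial.

The behavioural model is a *humidistat*: a correlated random walk on the
folded gradient angle whose drift pushes the animal toward the angle where
the local VPD equals its personal target VPD,

    target_i = target_vpd + mass_slope * (log m_i - mean log m) + b_i,
    b_i ~ Normal(0, animal_intercept_sd).

Because the target is a VPD, not an RH, the simulated cohort selects a
higher RH at the warmer temperature purely through psychrometrics -- the
signature the statistical models are meant to detect.  The walk reflects at
the dry (0 deg) and humid (180 deg) ends; the two mirrored half-gradients are
statistically identical, so the state is kept one-dimensional and unfolded
onto a randomly chosen half only when pixel coordinates are emitted.

Physiology: EWL scales allometrically with body mass and linearly with the
selected VPD (multiplicative lognormal trial noise); ReR follows a Q10 law
(default Q10 = 2.5) anchored at 17 degC.  Sex is carried as metadata but has
no effect, matching a design that fits no sex term.

Default magnitudes emulate the study cohort: lognormal body masses with mean
12 g and SD 4 g, selected VPD ~0.56 kPa with between-animal repeatability
(ICC) ~0.25, total distance ~40 m per trial, EWL ~0.07 ml/h and ReR ~0.18
ml/h at 17 degC, and station-noise levels that put the fitted field R^2 in
the 0.80-0.90 band.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arena as arena_mod
from . import psychro, tracks, water
from .arena import ArenaSpec, HumidityField
from .tracks import TrialMeta, Trajectory

__all__ = [
    "FieldTruth",
    "StudyConfig",
    "StudyTables",
    "make_cohort",
    "true_field",
    "simulate_logger_records",
    "simulate_trajectory",
    "simulate_water_records",
    "simulate_study_tables",
    "generate_study",
]


@dataclass(frozen=True)
class FieldTruth:
    """True linear RH profile of the gradient at one temperature."""

    rh_dry_pct: float
    rh_humid_pct: float
    station_noise_sd_pct: float = 6.4


@dataclass(frozen=True)
class StudyConfig:
    """All generator knobs; defaults are the emulated study conditions."""

    n_animals: int = 44
    temperatures: tuple[float, float] = (17.0, 22.0)
    n_frames: int = 1440
    frame_interval_s: float = 30.0
    trial_duration_h: float = 12.0
    # cohort
    mass_mean_g: float = 12.0
    mass_sd_g: float = 4.0
    mass_trial_jitter_sd: float = 0.01  # lognormal-scale between-trial jitter
    # humidistat behaviour
    target_vpd_kPa: float = 0.56
    vpd_target_mass_slope: float = 0.05  # kPa per log-g
    # The walk only partially transmits the personal target to the realised
    # trial median (slope ~0.26 under the default dynamics), so the intercept
    # SD is calibrated on the *realised* scale to give a VPD-model ICC ~ 0.25.
    animal_intercept_sd_kPa: float = 0.16
    bias_strength_deg_per_kPa: float = 0.8  # drift gain toward the target VPD
    step_angle_sd_deg: float = 6.2  # innovation SD of the walk
    persistence: float = 0.5  # correlated-walk memory
    radial_jitter_cm: float = 2.0
    # gradient field per temperature: RH spans put the cohort target VPD at
    # the 90 deg midpoint of the gradient; station noise puts the fitted
    # calibration R^2 in the physical build's 0.80-0.90 band.
    field_truth: dict = dc_field(
        default_factory=lambda: {
            17.0: FieldTruth(rh_dry_pct=48.0, rh_humid_pct=95.0, station_noise_sd_pct=6.4),
            22.0: FieldTruth(rh_dry_pct=60.0, rh_humid_pct=97.5, station_noise_sd_pct=5.3),
        }
    )
    logger_duration_h: float = 24.0
    logger_interval_s: float = 60.0
    logger_temperature_noise_sd_C: float = 0.15
    # physiology
    ewl_coeff: float = 0.0236  # ml/h per g^exponent per kPa
    ewl_mass_exponent: float = 0.67  # surface-area allometry
    ewl_vpd_exponent: float = 1.0
    ewl_noise_sd: float = 0.35  # lognormal trial noise
    rer_base_ml_per_h: float = 0.18  # at 17 degC
    rer_q10: float = 2.5
    rer_noise_sd: float = 0.4
    master_seed: int = 0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.n_frames < 2:
            raise ValueError("need at least two frames per trial")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("test temperatures must be distinct")
        for name in (
            "mass_sd_g",
            "animal_intercept_sd_kPa",
            "step_angle_sd_deg",
            "ewl_noise_sd",
            "rer_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _trial_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), *map(int, keys)))


def make_cohort(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Draw the animal cohort: ids, balanced sexes, masses and personal targets.

    Masses are lognormal with the configured arithmetic mean and SD; each
    animal's humidistat target is the cohort target plus a mass-dependent
    shift and a normal individual intercept (the source of repeatability).
    Deterministic for a fixed seed.
    """
    rng = _rng(_trial_seed(seed, 1))
    n = config.n_animals
    ids = [f"A{i + 1:02d}" for i in range(n)]
    sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    sigma2 = np.log1p((config.mass_sd_g / config.mass_mean_g) ** 2)
    mu = np.log(config.mass_mean_g) - sigma2 / 2.0
    masses = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    intercepts = rng.normal(0.0, config.animal_intercept_sd_kPa, size=n)
    log_m = np.log(masses)
    targets = (
        config.target_vpd_kPa
        + config.vpd_target_mass_slope * (log_m - log_m.mean())
        + intercepts
    )
    return pd.DataFrame(
        {
            "animal_id": ids,
            "sex": sexes,
            "mass_g": masses,
            "individual_intercept_kPa": intercepts,
            "target_vpd_kPa": targets,
        }
    )


def true_field(config: StudyConfig, temperature_C: float) -> HumidityField:
    """The noiseless linear angle->RH field the agent actually experiences."""
    truth = config.field_truth[temperature_C]
    slope = (truth.rh_humid_pct - truth.rh_dry_pct) / 180.0
    return HumidityField(
        nominal_temperature_C=temperature_C,
        intercept_pct=truth.rh_dry_pct,
        slope_pct_per_deg=slope,
        fit_r2=1.0,
        residual_sd_pct=0.0,
    )


def simulate_logger_records(
    config: StudyConfig, temperature_C: float, seed: int
) -> pd.DataFrame:
    """Hygro-logger records at the nine 22.5 deg stations with sensor noise.

    Gaussian per-record RH noise (station-independent) around the true linear
    profile, clipped to [0, 100]; its SD is chosen so the fitted field R^2
    lands near the physical build's ~0.85.
    """
    truth = config.field_truth[temperature_C]
    rng = _rng(_trial_seed(seed, 2, round(temperature_C * 10)))
    stations = np.asarray(arena_mod.CALIBRATION_STATIONS_DEG)
    n_t = int(config.logger_duration_h * 3600.0 / config.logger_interval_s)
    times = np.arange(n_t) * config.logger_interval_s
    fld = true_field(config, temperature_C)
    rows = []
    for s in stations:
        rh = arena_mod.field_rh_at(fld, s) + rng.normal(
            0.0, truth.station_noise_sd_pct, size=n_t
        )
        rows.append(
            pd.DataFrame(
                {
                    "timestamp": times,
                    "temperature_c": temperature_C
                    + rng.normal(0.0, config.logger_temperature_noise_sd_C, size=n_t),
                    "rh_pct": np.clip(rh, 0.0, 100.0),
                    "station_angle_deg": s,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _folded_walk(
    n_frames: int,
    target_vpd: float,
    fld: HumidityField,
    config: StudyConfig,
    rng: np.random.Generator,
    start_deg: float = 90.0,
) -> np.ndarray:
    """Reflected correlated random walk on the folded angle with VPD-seeking drift."""
    es = psychro.saturation_vapour_pressure(fld.nominal_temperature_C)
    vpd0 = es * (1.0 - fld.intercept_pct / 100.0)
    dvpd = -es * fld.slope_pct_per_deg / 100.0  # kPa per deg, negative toward humid
    if config.step_angle_sd_deg == 0.0 and config.bias_strength_deg_per_kPa == 0.0:
        raise ValueError("degenerate walk: zero step variance and zero bias")
    direction = -np.sign(dvpd) if dvpd != 0.0 else 0.0
    eps = rng.normal(0.0, config.step_angle_sd_deg, size=n_frames - 1)
    out = np.empty(n_frames)
    out[0] = f = start_deg
    v = 0.0
    bias = config.bias_strength_deg_per_kPa
    phi = config.persistence
    for t in range(n_frames - 1):
        vpd_here = vpd0 + dvpd * f
        v = phi * v + bias * (vpd_here - target_vpd) * direction + eps[t]
        f += v
        while f < 0.0 or f > 180.0:
            if f < 0.0:
                f = -f
            else:
                f = 360.0 - f
            v = -v
        out[t + 1] = f
    return out


def simulate_trajectory(
    animal: pd.Series,
    fld: HumidityField,
    temperature_C: float,
    config: StudyConfig,
    seed: int,
    lane: str = "outer",
    arena: ArenaSpec | None = None,
) -> Trajectory:
    """Simulate one trial and emit it as pixel-space tracking data.

    The walk starts at the intermediate station (90 deg), matching release
    through the intermediate compartment.  The folded path is unfolded onto a
    randomly chosen mirror half and mapped to image pixels through the
    arena's centroid and scale, so the full ingest path (re-centring, polar
    conversion, folding) is exercised on read-back.  Bit-identical for a
    fixed seed.
    """
    if fld.nominal_temperature_C != temperature_C:
        raise ValueError("field temperature does not match trial temperature")
    arena = arena or ArenaSpec()
    rng = _rng(seed)
    folded = _folded_walk(
        config.n_frames, float(animal["target_vpd_kPa"]), fld, config, rng
    )
    branch = rng.choice([1.0, -1.0])
    theta = (branch * folded) % 360.0
    lane_r = arena.lane_radius_cm(lane)
    half_width = min(
        config.radial_jitter_cm,
        0.45 * (arena.lane_partition_radius_cm - arena.inner_radius_cm),
    )
    radius_cm = lane_r + rng.uniform(-half_width, half_width, size=config.n_frames)
    r_px = radius_cm * arena.px_per_cm
    th = np.radians(theta)
    cx, cy = arena.centroid_px
    frames = pd.DataFrame(
        {
            "frame_index": np.arange(1, config.n_frames + 1),
            "time_s": np.arange(config.n_frames) * config.frame_interval_s,
            "x_px": cx + r_px * np.cos(th),
            "y_px": cy + r_px * np.sin(th),
            "interpolated": False,
        }
    )
    meta = TrialMeta(
        animal_id=str(animal["animal_id"]),
        sex=str(animal["sex"]),
        test_temperature_C=temperature_C,
        lane=lane,
    )
    return Trajectory(meta=meta, frames=frames, frame_interval_s=config.frame_interval_s)


def simulate_water_records(
    animal: pd.Series,
    summary: tracks.AnimalSummary,
    config: StudyConfig,
    seed: int,
) -> water.WaterRecord:
    """Simulate the three weighings of one trial from its behavioural summary.

    EWL = coeff * mass^b * VPD^c * lognormal noise; post-trial mass follows
    gravimetrically.  ReR obeys the configured Q10 law anchored at 17 degC;
    the rehydrated mass is capped at the pre-trial mass (animals at most
    regain their initial mass).
    """
    rng = _rng(seed)
    t_ref = min(config.temperatures)
    mass_pre = float(animal["mass_g"]) * float(
        np.exp(rng.normal(0.0, config.mass_trial_jitter_sd))
    )
    ewl = (
        config.ewl_coeff
        * mass_pre**config.ewl_mass_exponent
        * max(summary.median_selected_vpd_kPa, 1e-6) ** config.ewl_vpd_exponent
        * float(np.exp(rng.normal(0.0, config.ewl_noise_sd)))
    )
    mass_post = mass_pre - ewl * config.trial_duration_h
    if mass_post <= 0.0:
        raise ValueError(
            f"simulated EWL {ewl:.3f} ml/h would exhaust body mass {mass_pre:.2f} g"
        )
    rer = (
        config.rer_base_ml_per_h
        * config.rer_q10 ** ((summary.test_temperature_C - t_ref) / 10.0)
        * float(np.exp(rng.normal(0.0, config.rer_noise_sd)))
    )
    mass_rehydrated = min(mass_post + rer * 0.5, mass_pre)
    return water.water_record(
        animal_id=summary.animal_id,
        test_temperature_C=summary.test_temperature_C,
        mass_pre_g=mass_pre,
        mass_post_g=mass_post,
        mass_rehydrated_g=mass_rehydrated,
        trial_duration_h=config.trial_duration_h,
    )


@dataclass
class StudyTables:
    """In-memory bundle of one simulated study."""

    cohort: pd.DataFrame
    fitted_fields: dict
    true_fields: dict
    summaries: pd.DataFrame
    water_records: pd.DataFrame
    analysis_table: pd.DataFrame
    truth: dict


def _truth_dict(config: StudyConfig, cohort: pd.DataFrame) -> dict:
    d = dataclasses.asdict(config)
    d["field_truth"] = {str(k): dataclasses.asdict(v) for k, v in config.field_truth.items()}
    t1, t2 = sorted(config.temperatures)
    rh = {
        t: psychro.rh_from_vpd(t, config.target_vpd_kPa) for t in (t1, t2)
    }
    d["implied_rh_at_target_vpd_pct"] = rh
    d["implied_rh_temperature_offset_pct"] = rh[t2] - rh[t1]
    d["cohort_mass_mean_g"] = float(cohort["mass_g"].mean())
    return d


def simulate_study_tables(
    config: StudyConfig,
    seed: int,
    arena: ArenaSpec | None = None,
) -> StudyTables:
    """Run the whole synthetic study in memory.

    Draws the cohort, calibrates fitted fields from simulated logger records,
    simulates every trial, reduces each to its behavioural summary (using the
    *fitted* fields, as the real pipeline would), simulates the weighings and
    assembles the joined analysis table (one row per animal x temperature).
    """
    from . import pipeline

    arena = arena or ArenaSpec()
    cohort = make_cohort(config, seed)
    fitted_fields, true_fields = {}, {}
    for t in config.temperatures:
        true_fields[t] = true_field(config, t)
        log = simulate_logger_records(config, t, seed)
        fitted_fields[t] = arena_mod.fit_humidity_field(log, t)

    summaries, records = [], []
    lanes = ["inner", "outer"]
    for i, animal in cohort.iterrows():
        for j, t in enumerate(config.temperatures):
            sseq = _trial_seed(seed, 3, i, round(t * 10))
            traj = simulate_trajectory(
                animal, true_fields[t], t, config, sseq, lane=lanes[(i + j) % 2], arena=arena
            )
            _, exp = tracks.split_periods(traj)
            summary = tracks.summarize_animal(exp, fitted_fields[t], arena)
            rec = simulate_water_records(
                animal, summary, config, _trial_seed(seed, 4, i, round(t * 10))
            )
            summaries.append(summary)
            records.append(rec)
    summaries_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    water_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    table = pipeline.build_analysis_table(summaries_df, water_df)
    return StudyTables(
        cohort=cohort,
        fitted_fields=fitted_fields,
        true_fields=true_fields,
        summaries=summaries_df,
        water_records=water_df,
        analysis_table=table,
        truth=_truth_dict(config, cohort),
    )


def generate_study(config: StudyConfig, seed: int, out_dir) -> dict:
    """Write the full synthetic study to disk as plain-text files.

    Produces one Fiji-style tracking CSV per trial, one hygro-logger CSV per
    temperature, the mass-record CSV, a trial manifest binding files to
    metadata, and ``truth.json`` with every true generator parameter for
    recovery tests.  Byte-identical for a fixed seed.  Returns the bundle
    paths.
    """
    out = Path(out_dir)
    tracking_dir = out / "tracking"
    tracking_dir.mkdir(parents=True, exist_ok=True)
    arena = ArenaSpec()
    tables = simulate_study_tables(config, seed, arena=arena)

    manifest_rows = []
    cohort = tables.cohort
    lanes = ["inner", "outer"]
    for i, animal in cohort.iterrows():
        for j, t in enumerate(config.temperatures):
            sseq = _trial_seed(seed, 3, i, round(t * 10))
            traj = simulate_trajectory(
                animal,
                tables.true_fields[t],
                t,
                config,
                sseq,
                lane=lanes[(i + j) % 2],
                arena=arena,
            )
            fname = f"{animal['animal_id']}_{t:g}C.csv"
            df = pd.DataFrame(
                {
                    "Track n°": 1,
                    "Slice n°": traj.frames["frame_index"],
                    "X": traj.frames["x_px"].round(2),
                    "Y": traj.frames["y_px"].round(2),
                }
            )
            df.to_csv(tracking_dir / fname, index=False)
            manifest_rows.append(
                {
                    "file": f"tracking/{fname}",
                    "animal_id": animal["animal_id"],
                    "sex": animal["sex"],
                    "temperature_c": t,
                    "lane": lanes[(i + j) % 2],
                    "frame_interval_s": config.frame_interval_s,
                }
            )

    logger_paths = {}
    for t in config.temperatures:
        log = simulate_logger_records(config, t, seed)
        log["temperature_c"] = log["temperature_c"].round(2)
        log["rh_pct"] = log["rh_pct"].round(2)
        p = out / f"logger_{t:g}C.csv"
        log.to_csv(p, index=False)
        logger_paths[t] = p

    mass = tables.water_records.rename(columns={"test_temperature_C": "temperature_c"})
    mass = mass.merge(cohort[["animal_id", "sex"]], on="animal_id")
    mass_cols = ["animal_id", "sex", "temperature_c", "mass_pre_g", "mass_post_g", "mass_rehydrated_g"]
    mass_path = out / "masses.csv"
    mass[mass_cols].round(4).to_csv(mass_path, index=False)

    manifest_path = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(tables.truth, indent=2, default=float))
    return {
        "manifest": manifest_path,
        "tracking_dir": tracking_dir,
        "loggers": logger_paths,
        "masses": mass_path,
        "truth": truth_path,
    }
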