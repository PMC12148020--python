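"""Ingest of Fiji Manual-Tracking output and reduction to per-animal summaries.

A trial yields one image every 30 s for 12 h (1440 frames); the mid-body
position of the animal in each image is a row of a Manual-Tracking CSV.  The
first 3 h are habituation and are excluded from all hypothesis-level
summaries; the remaining 9 h are the experimental period.

Per-animal outcomes are the median selected RH and median selected VPD over
the experimental period (position -> folded gradient angle -> calibrated
humidity field) and the total distance moved ``D_t`` (sum of per-step minimal
arcs at the lane's mean radius).  Because VPD is a strictly decreasing
function of RH at fixed temperature, the median commutes with the
transformation: ``median(VPD) == VPD(median(RH))`` within a constant-
temperature trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import arena as arena_mod
from .arena import ArenaSpec, HumidityField

__all__ = [
    "TrialMeta",
    "Trajectory",
    "AnimalSummary",
    "TrackFormatError",
    "TrackQualityError",
    "read_manual_tracking",
    "split_periods",
    "summarize_animal",
]

HABITUATION_S = 3 * 3600.0

#: Default Fiji Manual-Tracking column mapping.  Keys are canonical names,
#: values are accepted CSV headers (first match wins).
DEFAULT_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "track": ("Track n°", "Track no", "track", "track_id"),
    "slice": ("Slice n°", "Slice no", "slice", "frame"),
    "x": ("X", "x", "x_px"),
    "y": ("Y", "y", "y_px"),
}


class TrackFormatError(ValueError):
    """Raised when a tracking file does not have the expected columns."""


class TrackQualityError(ValueError):
    """Raised when a track has too many missing frames to trust."""


@dataclass(frozen=True)
class TrialMeta:
    """Identity and conditions of one trial."""

    animal_id: str
    sex: str
    test_temperature_C: float
    lane: str  # 'inner' or 'outer'


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-frame positions of one animal in one trial.

    ``frames`` holds columns frame_index (1-based), time_s, x_px, y_px and an
    ``interpolated`` flag for frames filled across single-slice gaps.
    """

    meta: TrialMeta
    frames: pd.DataFrame
    frame_interval_s: float = 30.0
    n_flagged: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        t = self.frames["time_s"].to_numpy()
        return float(t[-1] - t[0]) if len(t) else 0.0


@dataclass(frozen=True)
class AnimalSummary:
    """Per-trial derived outcomes used in the statistical models."""

    animal_id: str
    sex: str
    test_temperature_C: float
    median_selected_vpd_kPa: float
    median_selected_rh_pct: float
    total_distance_m: float
    n_experimental_frames: int


def _resolve_columns(df: pd.DataFrame, columns: Mapping[str, tuple[str, ...]]):
    resolved = {}
    for canon, candidates in columns.items():
        for cand in candidates:
            if cand in df.columns:
                resolved[canon] = cand
                break
        else:
            raise TrackFormatError(
                f"no column for {canon!r}; expected one of {candidates}, "
                f"got header {list(df.columns)}"
            )
    return resolved


def read_manual_tracking(
    path,
    trial_meta: TrialMeta,
    frame_interval_s: float = 30.0,
    columns: Mapping[str, tuple[str, ...]] = DEFAULT_COLUMNS,
    max_missing_frac: float = 0.05,
) -> Trajectory:
    """Read one Fiji Manual-Tracking CSV into a :class:`Trajectory`.

    Rows are sorted by slice number; a missing interior slice is filled by
    linear interpolation of (x, y) and flagged.  Leading/trailing gaps are
    never extrapolated (the trajectory simply starts/ends at its first/last
    observed slice).  More than ``max_missing_frac`` missing interior slices
    is a quality error.  Frame timestamps are reconstructed as
    ``(slice - 1) * frame_interval_s``.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df, columns)
    track_ids = df[cols["track"]].unique()
    if len(track_ids) != 1:
        raise TrackFormatError(
            f"{path}: expected a single track per file, found {len(track_ids)}"
        )
    df = df.sort_values(cols["slice"], kind="mergesort")
    slices = df[cols["slice"]].to_numpy(dtype=int)
    if len(np.unique(slices)) != len(slices):
        raise TrackFormatError(f"{path}: duplicate slice numbers")

    full = np.arange(slices[0], slices[-1] + 1)
    missing = np.setdiff1d(full, slices)
    if full.size >= 2 and missing.size / full.size > max_missing_frac:
        raise TrackQualityError(
            f"{path}: track {track_ids[0]!r} is missing {missing.size} of "
            f"{full.size} slices (> {max_missing_frac:.0%})"
        )
    x = np.interp(full, slices, df[cols["x"]].to_numpy(dtype=float))
    y = np.interp(full, slices, df[cols["y"]].to_numpy(dtype=float))
    interpolated = np.isin(full, missing)
    frames = pd.DataFrame(
        {
            "frame_index": full,
            "time_s": (full - 1) * frame_interval_s,
            "x_px": x,
            "y_px": y,
            "interpolated": interpolated,
        }
    ).reset_index(drop=True)
    return Trajectory(
        meta=trial_meta,
        frames=frames,
        frame_interval_s=frame_interval_s,
        n_flagged=int(interpolated.sum()),
    )


def split_periods(trajectory: Trajectory) -> tuple[Trajectory, Trajectory]:
    """Split a trial into (habituation, experimental) at the 3 h mark.

    Habituation is every frame with ``time_s < 10800``; for a full 1440-frame
    trial this is the 360/1080 split.  A trial spanning under 3 h has no
    experimental period and is rejected.
    """
    if trajectory.duration_s < HABITUATION_S:
        raise ValueError(
            f"trial spans {trajectory.duration_s / 3600:.2f} h < 3 h habituation"
        )
    mask = trajectory.frames["time_s"] < HABITUATION_S
    hab = trajectory.frames[mask].reset_index(drop=True)
    exp = trajectory.frames[~mask].reset_index(drop=True)
    return (
        replace(trajectory, frames=hab, n_flagged=int(hab["interpolated"].sum())),
        replace(trajectory, frames=exp, n_flagged=int(exp["interpolated"].sum())),
    )


def derive_angles(trajectory: Trajectory, arena: ArenaSpec) -> pd.DataFrame:
    """Per-frame polar and folded angles for a trajectory (adds columns)."""
    frames = trajectory.frames
    _, theta = arena_mod.cartesian_to_polar(
        frames["x_px"].to_numpy(), frames["y_px"].to_numpy(), arena.centroid_px
    )
    out = frames.copy()
    out["theta_deg"] = np.atleast_1d(theta)
    out["folded_angle_deg"] = arena_mod.gradient_coordinate(out["theta_deg"].to_numpy())
    return out


def summarize_animal(
    experimental: Trajectory, field: HumidityField, arena: ArenaSpec
) -> AnimalSummary:
    """Reduce an experimental-period trajectory to its behavioural summary.

    Selected RH/VPD are the per-frame field values at the folded angle; the
    medians use the midpoint-of-middle-two convention (numpy default), which
    preserves ``median(VPD) == VPD(median(RH))`` at fixed temperature.  The
    calibration field must match the trial temperature.
    """
    if experimental.n_frames == 0:
        raise ValueError("empty experimental trajectory")
    if field.nominal_temperature_C != experimental.meta.test_temperature_C:
        raise ValueError(
            f"field temperature {field.nominal_temperature_C} degC does not match "
            f"trial temperature {experimental.meta.test_temperature_C} degC"
        )
    frames = derive_angles(experimental, arena)
    folded = frames["folded_angle_deg"].to_numpy()
    rh = arena_mod.field_rh_at(field, folded)
    vpd = arena_mod.field_vpd_at(field, folded)
    lane_r = arena.lane_radius_cm(experimental.meta.lane)
    if len(frames) >= 2:
        dist_m = arena_mod.total_distance(frames["theta_deg"].to_numpy(), lane_r)
    else:
        dist_m = 0.0
    return AnimalSummary(
        animal_id=experimental.meta.animal_id,
        sex=experimental.meta.sex,
        test_temperature_C=experimental.meta.test_temperature_C,
        median_selected_vpd_kPa=float(np.median(vpd)),
        median_selected_rh_pct=float(np.median(rh)),
        total_distance_m=dist_m,
        n_experimental_frames=len(frames),
    )
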