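"""Geometry and calibration of the annular humidity gradient.

The arena is a ring (outer radius 45 cm, inner radius 30 cm) split into an
inner and an outer lane.  Dry air enters at 0 deg, humid air at 180 deg, and
mixed air at the two mirrored 90 deg ports, so humidity varies with angle and
the arena is mirror-symmetric about the dry-humid axis.  Position along the
gradient is therefore indexed by the *folded* angle in [0, 180]: the angular
distance from the dry port, identical for the two mirrored half-gradients.

Tracking coordinates arrive in image space (origin top-left, y down).  After
re-centring on the annulus centroid they are converted to polar coordinates;
with the image y-axis pointing down, the polar angle increases clockwise on
screen.  Distances moved between frames are arc lengths ``r * dtheta`` at the
lane's mean radius, with the minimal (wrap-aware) angular separation.

The angle-to-humidity calibration is an ordinary least-squares line of logged
RH against folded station angle, fitted to hygro-logger records taken at
stations every 22.5 deg; its R^2 quantifies how linear the realised gradient
is (the physical build achieves ~0.85).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import psychro

__all__ = [
    "ArenaSpec",
    "CalibrationRecord",
    "HumidityField",
    "cartesian_to_polar",
    "gradient_coordinate",
    "arc_distance",
    "total_distance",
    "fit_humidity_field",
    "field_rh_at",
    "field_vpd_at",
    "read_logger_csv",
]

#: Angular stations (deg, folded coordinate) at which hygro-loggers sit.
CALIBRATION_STATIONS_DEG = tuple(np.arange(0.0, 180.1, 22.5))


@dataclass(frozen=True)
class ArenaSpec:
    """Physical layout of the annular gradient and the image mapping.

    ``px_per_cm`` is the image scale, taken from the known outer radius
    (45 cm) versus its pixel radius in a calibration image.
    """

    outer_radius_cm: float = 45.0
    inner_radius_cm: float = 30.0
    lane_partition_radius_cm: float = 37.5
    dry_angle_deg: float = 0.0
    intermediate_angle_deg: float = 90.0
    humid_angle_deg: float = 180.0
    frame_interval_s: float = 30.0
    centroid_px: tuple[float, float] = (500.0, 500.0)
    px_per_cm: float = 10.0

    def __post_init__(self):
        if not (self.inner_radius_cm < self.lane_partition_radius_cm < self.outer_radius_cm):
            raise ValueError(
                "lane partition radius must lie strictly between the inner and outer radii"
            )

    def lane_radius_cm(self, lane: str) -> float:
        """Mean radius of the named lane ('inner' or 'outer'), in cm."""
        if lane == "inner":
            return 0.5 * (self.inner_radius_cm + self.lane_partition_radius_cm)
        if lane == "outer":
            return 0.5 * (self.lane_partition_radius_cm + self.outer_radius_cm)
        raise ValueError(f"unknown lane {lane!r}; expected 'inner' or 'outer'")


@dataclass(frozen=True)
class CalibrationRecord:
    """One hygro-logger reading at a known angular station."""

    station_angle_deg: float
    timestamp_s: float
    temperature_C: float
    rh_pct: float


@dataclass(frozen=True)
class HumidityField:
    """Fitted linear mapping from folded angle to RH at a nominal temperature.

    ``rh = intercept_pct + slope_pct_per_deg * folded_angle`` with the
    prediction clipped to [0, 100].  ``fit_r2`` is the coefficient of
    determination of the per-record fit and ``residual_sd_pct`` the standard
    deviation of its residuals.
    """

    nominal_temperature_C: float
    intercept_pct: float
    slope_pct_per_deg: float
    fit_r2: float
    residual_sd_pct: float
    station_means: dict = field(default_factory=dict, compare=False)

    def to_json(self, path) -> None:
        payload = {
            "nominal_temperature_C": self.nominal_temperature_C,
            "intercept_pct": self.intercept_pct,
            "slope_pct_per_deg": self.slope_pct_per_deg,
            "fit_r2": self.fit_r2,
            "residual_sd_pct": self.residual_sd_pct,
            "station_means": {str(k): v for k, v in self.station_means.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "HumidityField":
        d = json.loads(Path(path).read_text())
        return cls(
            nominal_temperature_C=d["nominal_temperature_C"],
            intercept_pct=d["intercept_pct"],
            slope_pct_per_deg=d["slope_pct_per_deg"],
            fit_r2=d["fit_r2"],
            residual_sd_pct=d["residual_sd_pct"],
            station_means={float(k): v for k, v in d.get("station_means", {}).items()},
        )


def cartesian_to_polar(x_px, y_px, centroid_px) -> tuple:
    """Re-centre image coordinates on the annulus centroid and convert to polar.

    Returns ``(radius_px, theta_deg)`` with ``theta_deg`` in [0, 360).  The
    image y-axis points down, so theta increases clockwise on screen; theta=0
    points along +x (the dry-port reference direction).  Accepts scalars or
    arrays; a point exactly at the centroid has no defined angle and is
    rejected.
    """
    cx, cy = centroid_px
    dx = np.asarray(x_px, dtype=float) - cx
    dy = np.asarray(y_px, dtype=float) - cy
    r = np.hypot(dx, dy)
    if np.any(r == 0.0):
        raise ValueError("point coincides with the arena centroid; angle undefined")
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    if r.ndim == 0:
        return float(r), float(theta)
    return r, theta


def gradient_coordinate(theta_deg):
    """Fold a polar angle onto the dry->humid axis: returns an angle in [0, 180].

    0 is the dry station, 180 the humid station; the two mirrored
    half-gradients map onto each other.  Idempotent.
    """
    t = np.asarray(theta_deg, dtype=float) % 360.0
    folded = np.minimum(t, 360.0 - t)
    return folded if folded.ndim else float(folded)


def arc_distance(theta1_deg, theta2_deg, lane_radius_cm):
    """Arc length (cm) between two polar angles at the lane's mean radius.

    Uses the minimal angular separation (wrap-aware): a 30 s step cannot
    plausibly exceed half the annulus.  Symmetric in the two angles and
    bounded by ``pi * lane_radius_cm``.
    """
    if np.any(np.asarray(lane_radius_cm, dtype=float) <= 0.0):
        raise ValueError(f"lane radius must be positive, got {lane_radius_cm!r}")
    d = (np.asarray(theta2_deg, dtype=float) - np.asarray(theta1_deg, dtype=float)) % 360.0
    sep = np.minimum(d, 360.0 - d)
    out = lane_radius_cm * np.radians(sep)
    return out if np.ndim(out) else float(out)


def total_distance(trajectory_angles_deg: Sequence[float], lane_radius_cm: float) -> float:
    """Total distance moved (m): sum of consecutive minimal-arc steps.

    Requires at least two frames.  The per-step arcs are in cm; the total is
    returned in metres.
    """
    theta = np.asarray(trajectory_angles_deg, dtype=float)
    if theta.size < 2:
        raise ValueError("total distance needs at least 2 frames")
    steps_cm = arc_distance(theta[:-1], theta[1:], lane_radius_cm)
    return float(np.sum(steps_cm)) / 100.0


def fit_humidity_field(
    records: Sequence[CalibrationRecord] | pd.DataFrame,
    nominal_temperature_C: float,
) -> HumidityField:
    """Fit the angle->RH calibration line from hygro-logger records.

    The slope and intercept come from an ordinary least-squares fit of the
    per-record RH against folded station angle; R^2 and the residual SD are
    those of the per-record fit, so sensor noise lowers R^2 even when the
    station means are perfectly linear.  Requires records at >=3 distinct
    stations.  A zero-variance (flat) calibration is degenerate and reported
    with slope 0 and R^2 = 0 by convention, keeping the pipeline total.
    """
    if isinstance(records, pd.DataFrame):
        angles = records["station_angle_deg"].to_numpy(dtype=float)
        rh = records["rh_pct"].to_numpy(dtype=float)
    else:
        angles = np.array([r.station_angle_deg for r in records], dtype=float)
        rh = np.array([r.rh_pct for r in records], dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("calibration RH outside [0, 100] %")
    if np.any((angles < 0.0) | (angles > 180.0)):
        raise ValueError("station angles must lie on the folded coordinate [0, 180] deg")
    stations = np.unique(angles)
    if stations.size < 3:
        raise ValueError(f"need records at >=3 distinct stations, got {stations.size}")

    station_means = {
        float(s): float(np.mean(rh[angles == s])) for s in stations
    }
    ss_tot = float(np.sum((rh - rh.mean()) ** 2))
    if ss_tot == 0.0:
        # flat input: no humidity signal at all
        return HumidityField(
            nominal_temperature_C=float(nominal_temperature_C),
            intercept_pct=float(rh.mean()),
            slope_pct_per_deg=0.0,
            fit_r2=0.0,
            residual_sd_pct=0.0,
            station_means=station_means,
        )
    slope, intercept = np.polyfit(angles, rh, 1)
    resid = rh - (intercept + slope * angles)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return HumidityField(
        nominal_temperature_C=float(nominal_temperature_C),
        intercept_pct=float(intercept),
        slope_pct_per_deg=float(slope),
        fit_r2=r2,
        residual_sd_pct=float(np.std(resid, ddof=2)) if resid.size > 2 else 0.0,
        station_means=station_means,
    )


def field_rh_at(field: HumidityField, folded_angle_deg):
    """RH (%) predicted by the calibration at a folded angle, clipped to [0, 100]."""
    a = np.asarray(folded_angle_deg, dtype=float)
    if np.any((a < 0.0) | (a > 180.0)):
        raise ValueError(f"folded angle {folded_angle_deg!r} outside [0, 180] deg")
    rh = np.clip(field.intercept_pct + field.slope_pct_per_deg * a, 0.0, 100.0)
    return rh if rh.ndim else float(rh)


def field_vpd_at(field: HumidityField, folded_angle_deg):
    """VPD (kPa) at a folded angle: the field's RH through the psychrometric map
    at the field's nominal temperature."""
    return psychro.vpd_from_rh(field.nominal_temperature_C, field_rh_at(field, folded_angle_deg))


def read_logger_csv(path) -> pd.DataFrame:
    """Read a hygro-logger CSV (`timestamp,temperature_c,rh_pct,station_angle_deg`).

    Timestamps may be ISO-8601 strings or integer seconds; they are returned
    as seconds from the first record in column ``timestamp_s``.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "temperature_c", "rh_pct", "station_angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"logger CSV {path} missing columns {sorted(missing)}")
    ts = df["timestamp"]
    if pd.api.types.is_numeric_dtype(ts):
        seconds = ts.astype(float)
    else:
        parsed = pd.to_datetime(ts, format="ISO8601")
        seconds = (parsed - parsed.iloc[0]).dt.total_seconds()
    out = df.rename(columns={"temperature_c": "temperature_C"}).copy()
    out["timestamp_s"] = seconds - float(seconds.iloc[0])
    return out[["station_angle_deg", "timestamp_s", "temperature_C", "rh_pct"]]
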