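"""Psychrometric conversions between temperature, relative humidity and vapour pressure.

The vapour pressure deficit (VPD) is the drying power of air: the difference
between the saturated water vapour pressure ``WVP_sat(T)`` and the actual water
vapour pressure ``WVP_act = WVP_sat * RH/100``.  VPD, not RH, is the driving
force of evaporative water loss, which is why humidity selection in a
temperature-controlled gradient is summarised on the VPD scale.

Saturation vapour pressure uses a Tetens-form closed expression

    e_s(T) = a * exp(b * T / (T + c))   [kPa, T in deg C]

with the Campbell & Norman constants ``(a, b, c) = (0.611, 17.502, 240.97)`` by
default.  The classic Tetens constants ``(0.61078, 17.27, 237.3)`` can be
swapped in via :class:`TetensConstants`; the two variants agree to well under
1% over the physiological range used here.

All relative humidities are carried on the 0-100 percentage scale.  Values
strictly between 0 and 1 are rejected rather than rescaled, as they almost
certainly denote a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TetensConstants",
    "CAMPBELL_NORMAN",
    "CLASSIC_TETENS",
    "HumiditySample",
    "saturation_vapour_pressure",
    "vpd_from_rh",
    "rh_from_vpd",
    "humidity_sample",
]

#: Temperature range (deg C) accepted by the conversions.  Covers every
#: condition an amphibian humidity-gradient assay plausibly uses.
TEMPERATURE_RANGE_C = (-10.0, 50.0)


@dataclass(frozen=True)
class TetensConstants:
    """Constants of the Tetens-form saturation vapour pressure equation."""

    a_kPa: float
    b: float
    c_C: float


CAMPBELL_NORMAN = TetensConstants(a_kPa=0.611, b=17.502, c_C=240.97)
CLASSIC_TETENS = TetensConstants(a_kPa=0.61078, b=17.27, c_C=237.3)

#: Default constants used throughout the package.
DEFAULT_CONSTANTS = CAMPBELL_NORMAN


@dataclass(frozen=True)
class HumiditySample:
    """Psychrometric state at one point: temperature, RH and vapour pressures.

    Satisfies ``wvp_act_kPa = wvp_sat_kPa * rh_pct/100`` and
    ``vpd_kPa = wvp_sat_kPa - wvp_act_kPa >= 0`` by construction
    (see :func:`humidity_sample`).
    """

    temperature_C: float
    rh_pct: float
    wvp_sat_kPa: float
    wvp_act_kPa: float
    vpd_kPa: float


def _check_temperature(temperature_C) -> np.ndarray:
    t = np.asarray(temperature_C, dtype=float)
    lo, hi = TEMPERATURE_RANGE_C
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(
            f"temperature {temperature_C!r} degC outside supported range [{lo}, {hi}]"
        )
    return t


def _check_rh(rh_pct) -> np.ndarray:
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError(f"relative humidity {rh_pct!r} outside [0, 100] %")
    if np.any((rh > 0.0) & (rh < 1.0)):
        raise ValueError(
            f"relative humidity {rh_pct!r} lies in (0, 1); RH is carried as a "
            "percentage on the 0-100 scale, not a fraction"
        )
    return rh


def saturation_vapour_pressure(temperature_C, constants: TetensConstants = DEFAULT_CONSTANTS):
    """Saturated water vapour pressure ``WVP_sat`` in kPa at ``temperature_C``.

    Strictly positive and strictly increasing in temperature.  Accepts scalars
    or arrays; temperatures outside -10..50 degC are rejected.
    """
    t = _check_temperature(temperature_C)
    es = constants.a_kPa * np.exp(constants.b * t / (t + constants.c_C))
    return es if es.ndim else float(es)


def vpd_from_rh(temperature_C, rh_pct, constants: TetensConstants = DEFAULT_CONSTANTS):
    """Vapour pressure deficit (kPa) of air at ``temperature_C`` and ``rh_pct`` %.

    ``VPD = WVP_sat(T) * (1 - RH/100)``: zero at saturation, decreasing in RH
    at fixed temperature, increasing in temperature at fixed RH < 100%.
    """
    rh = _check_rh(rh_pct)
    es = np.asarray(saturation_vapour_pressure(temperature_C, constants))
    vpd = es * (1.0 - rh / 100.0)
    return vpd if vpd.ndim else float(vpd)


def rh_from_vpd(temperature_C, vpd_kPa, constants: TetensConstants = DEFAULT_CONSTANTS):
    """Relative humidity (%) that yields ``vpd_kPa`` at ``temperature_C``.

    Exact inverse of :func:`vpd_from_rh` at the same temperature.  A VPD above
    the saturation vapour pressure would imply a negative RH and is rejected.
    """
    vpd = np.asarray(vpd_kPa, dtype=float)
    es = np.asarray(saturation_vapour_pressure(temperature_C, constants))
    if np.any(vpd < 0.0):
        raise ValueError(f"VPD {vpd_kPa!r} kPa is negative")
    if np.any(vpd > es):
        raise ValueError(
            f"VPD {vpd_kPa!r} kPa exceeds saturation vapour pressure {es!r} kPa"
        )
    rh = 100.0 * (1.0 - vpd / es)
    return rh if rh.ndim else float(rh)


def humidity_sample(
    temperature_C: float, rh_pct: float, constants: TetensConstants = DEFAULT_CONSTANTS
) -> HumiditySample:
    """Construct the full psychrometric state at ``(temperature_C, rh_pct)``."""
    rh = float(_check_rh(rh_pct))
    es = saturation_vapour_pressure(temperature_C, constants)
    vpd = es * (1.0 - rh / 100.0)  # exactly 0 at saturation
    return HumiditySample(
        temperature_C=float(temperature_C),
        rh_pct=rh,
        wvp_sat_kPa=es,
        wvp_act_kPa=es - vpd,
        vpd_kPa=vpd,
    )
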