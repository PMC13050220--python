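"""Extraterrestrial radiation, day length and incident shortwave.

Daily extraterrestrial radiation R_a follows the standard astronomical
formulation (solar constant G_sc = 0.082 MJ m-2 min-1, solar declination,
inverse relative Earth-Sun distance and sunset hour angle), and surface
shortwave R_s follows the Angstrom-Prescott relation with the recommended
coefficients a_s = 0.25, b_s = 0.5 driven by relative sunshine duration.
The workflow converts R_a (MJ m-2 d-1) to R_s in W m-2 through the fixed
factor 23.1 used by this measurement chain (see docs/methods.md for a
discussion of that constant).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateInputError, PolarConditionError

#: Solar constant, MJ m-2 min-1.
G_SC = 0.082
#: Angstrom-Prescott coefficients (recommended values).
A_S = 0.25
B_S = 0.5
#: MJ m-2 d-1 -> W m-2 conversion used by this processing chain.
RS_UNIT_CONVERSION = 23.1


@dataclass(frozen=True)
class SolarGeometry:
    """Solar geometry for one site-day."""

    latitude_deg: float
    doy: int
    declination: float  # rad
    sunset_angle: float  # rad
    inv_distance: float  # dimensionless
    day_length: float  # hours


@dataclass(frozen=True)
class RadiationRecord:
    """Radiation quantities for one site-day."""

    ra: float  # extraterrestrial, MJ m-2 d-1
    rs: float  # incident shortwave, W m-2
    sunshine_fraction: float


def _check_doy(doy: int) -> int:
    doy = int(doy)
    if not 1 <= doy <= 366:
        raise DegenerateInputError(f"day of year {doy} outside [1, 366]")
    return doy


def latitude_radians(latitude_deg: float) -> float:
    """Degrees to radians for the site latitude."""
    return float(latitude_deg) * math.pi / 180.0


def solar_declination(doy: int) -> float:
    """Solar declination delta = 0.409 sin(2 pi J / 365 - 1.39), rad."""
    doy = _check_doy(doy)
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def inverse_earth_sun_distance(doy: int) -> float:
    """Inverse relative Earth-Sun distance d_r = 1 + 0.033 cos(2 pi J / 365)."""
    doy = _check_doy(doy)
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)


def sunset_hour_angle(
    latitude_rad: float, declination: float, clamp: bool = False
) -> float:
    """Sunset hour angle omega_s = arccos(-tan(phi) tan(delta)), rad.

    Outside |tan(phi) tan(delta)| <= 1 the sun never sets or never rises;
    that raises ``PolarConditionError`` unless ``clamp`` is set, in which
    case the argument is clipped to [-1, 1] (omega_s = pi or 0).
    """
    arg = -math.tan(latitude_rad) * math.tan(declination)
    if abs(arg) > 1.0:
        if not clamp:
            raise PolarConditionError(
                f"arccos argument {arg:.4f} outside [-1, 1]: polar day/night"
            )
        arg = max(-1.0, min(1.0, arg))
    return math.acos(arg)


def day_length(sunset_angle: float) -> float:
    """Day length N = (24 / pi) omega_s, hours."""
    if not 0.0 <= sunset_angle <= math.pi:
        raise DegenerateInputError(
            f"sunset angle {sunset_angle:.4f} outside [0, pi]"
        )
    return 24.0 / math.pi * sunset_angle


def day_of_year(month: int, day: int, mode: str = "calendar") -> int:
    """Day of year from month and day.

    mode 'calendar' (default) returns the true non-leap DOY.  mode
    'verbatim' evaluates the legacy shortcut ``int(275 M / 9 - 30 + D) - 2``
    exactly as written (truncation toward zero, no month or leap
    corrections); the shortcut matches the calendar only for March in
    non-leap years and yields J = -1 for Jan 1 — it is kept for
    traceability against workflows that used it.
    """
    month, day = int(month), int(day)
    if mode == "verbatim":
        if not (1 <= month <= 12 and 1 <= day <= 31):
            raise DegenerateInputError(f"invalid month/day {month}/{day}")
        return int(275.0 * month / 9.0 - 30.0 + day) - 2
    if mode == "calendar":
        try:
            date = _dt.date(2001, month, day)  # any non-leap year
        except ValueError as exc:
            raise DegenerateInputError(str(exc)) from exc
        return date.timetuple().tm_yday
    raise DegenerateInputError(f"unknown mode {mode!r}; use 'verbatim' or 'calendar'")


def extraterrestrial_radiation(doy: int, latitude_rad: float) -> float:
    """Daily extraterrestrial radiation R_a, MJ m-2 d-1.

    R_a = (24*60/pi) G_sc d_r (omega_s sin(phi) sin(delta)
                               + cos(phi) cos(delta) sin(omega_s)).
    """
    doy = _check_doy(doy)
    delta = solar_declination(doy)
    d_r = inverse_earth_sun_distance(doy)
    omega_s = sunset_hour_angle(latitude_rad, delta)
    ra = (
        24.0 * 60.0 / math.pi
        * G_SC
        * d_r
        * (
            omega_s * math.sin(latitude_rad) * math.sin(delta)
            + math.cos(latitude_rad) * math.cos(delta) * math.sin(omega_s)
        )
    )
    return max(ra, 0.0)


def incident_shortwave(
    ra: float,
    sunshine_fraction: float,
    a_s: float = A_S,
    b_s: float = B_S,
    conversion: float = RS_UNIT_CONVERSION,
) -> float:
    """Incident shortwave R_s = (a_s + b_s n/N) R_a * 23.1, W m-2."""
    if ra < 0:
        raise DegenerateInputError("extraterrestrial radiation must be >= 0")
    if not 0.0 <= sunshine_fraction <= 1.0:
        raise DegenerateInputError(
            f"sunshine fraction {sunshine_fraction} outside [0, 1]"
        )
    return (a_s + b_s * sunshine_fraction) * ra * conversion


def solar_geometry(latitude_deg: float, doy: int) -> SolarGeometry:
    """Full solar geometry for one site-day."""
    phi = latitude_radians(latitude_deg)
    delta = solar_declination(doy)
    omega_s = sunset_hour_angle(phi, delta)
    return SolarGeometry(
        latitude_deg=float(latitude_deg),
        doy=int(doy),
        declination=delta,
        sunset_angle=omega_s,
        inv_distance=inverse_earth_sun_distance(doy),
        day_length=day_length(omega_s),
    )


def radiation_record(
    latitude_deg: float, doy: int, sunshine_hours: float
) -> RadiationRecord:
    """R_a and R_s for one site-day from sunshine duration in hours."""
    geom = solar_geometry(latitude_deg, doy)
    frac = 0.0 if geom.day_length == 0 else sunshine_hours / geom.day_length
    frac = min(max(frac, 0.0), 1.0)
    ra = extraterrestrial_radiation(doy, latitude_radians(latitude_deg))
    return RadiationRecord(ra=ra, rs=incident_shortwave(ra, frac), sunshine_fraction=frac)


def process_weather_table(weather: pd.DataFrame) -> pd.DataFrame:
    """Augment a weather table with solar geometry and radiation columns.

    Expects columns ``date`` (ISO string or datetime), ``latitude_deg`` and
    ``sunshine_hours``; ``doy`` may be given directly instead of ``date``.
    Adds ``doy, declination, day_length_h, ra_mj, rs_wm2``.
    """
    out = weather.copy()
    if "doy" not in out.columns:
        dates = pd.to_datetime(out["date"])
        out["doy"] = dates.dt.dayofyear
    rows = []
    for _, row in out.iterrows():
        geom = solar_geometry(row["latitude_deg"], int(row["doy"]))
        rec = radiation_record(
            row["latitude_deg"], int(row["doy"]), float(row["sunshine_hours"])
        )
        rows.append(
            {
                "declination": geom.declination,
                "day_length_h": geom.day_length,
                "ra_mj": rec.ra,
                "rs_wm2": rec.rs,
            }
        )
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
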