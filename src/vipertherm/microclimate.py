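"""Hourly above-ground microclimate reconstruction from monthly climate normals.

Given twelve monthly mean air temperatures and diurnal ranges for a site,
this module reconstructs a full 24 x 365 hour year of the thermal
environment an animal at the surface experiences: air temperature, clear-sky
solar irradiance, effective sky temperature, substrate temperature and wind.
Future climates enter through additive monthly "warm" offsets (delta-method
downscaling): the offset is the difference between a fine-resolution (or
future) monthly climatology and the baseline one, added month by month.

The year has no leap day: hour index 0..8759 in local solar time (solar noon
at hour 12), day of year 1..365.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

HOURS_PER_YEAR = 8760
DAYS_PER_YEAR = 365

#: Day-of-year of each month's midpoint (day 15 of the month, no leap day).
MONTH_MIDPOINTS = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

SOLAR_CONSTANT = 1361.0  # W m^-2
ATMOSPHERIC_TRANSMITTANCE = 0.70  # clear-sky broadband transmittance
DIFFUSE_FRACTION = 0.3
PRESSURE_SCALE_HEIGHT_M = 8200.0

DAY_LAG_HOURS = 1.5  # lag of the afternoon temperature peak
NIGHT_DECAY_SHAPE = 2.5  # exponential shape of the nocturnal cooling curve
SUBSTRATE_SOLAR_COEFF = 1.0 / 50.0  # degC of substrate excess per W m^-2


@dataclass(frozen=True)
class MonthlyClimate:
    """Monthly mean air temperatures and diurnal temperature ranges (degC)."""

    tavg: np.ndarray
    dtr: np.ndarray

    def __post_init__(self) -> None:
        tavg = np.asarray(self.tavg, dtype=float)
        dtr = np.asarray(self.dtr, dtype=float)
        if tavg.shape != (12,) or dtr.shape != (12,):
            raise ValueError(
                f"monthly climate needs 12 values, got tavg {tavg.shape}, dtr {dtr.shape}"
            )
        if not (np.isfinite(tavg).all() and np.isfinite(dtr).all()):
            raise ValueError("non-finite monthly climate value")
        if (dtr < 0).any():
            raise ValueError("diurnal range must be non-negative")
        object.__setattr__(self, "tavg", tavg)
        object.__setattr__(self, "dtr", dtr)


@dataclass(frozen=True)
class WarmOffsets:
    """Twelve additive monthly air-temperature corrections (degC)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (12,):
            raise ValueError(f"offsets need 12 values, got shape {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("non-finite warm offset")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class EnvironmentHour:
    """The thermal environment of a single hour."""

    air_temp: float
    solar: float
    sky_temp: float
    substrate_temp: float
    wind: float


@dataclass
class HourlyEnvironment:
    """One simulated year (8760 h) of the above-ground thermal environment.

    All arrays have length 8760 and share the hour index: ``doy`` is the day
    of year (1..365) and ``hour`` the local solar hour (0..23) of each record.
    """

    air_temp: np.ndarray
    solar: np.ndarray
    sky_temp: np.ndarray
    substrate_temp: np.ndarray
    wind: np.ndarray
    doy: np.ndarray = field(default=None)
    hour: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.doy is None:
            self.doy = np.repeat(np.arange(1, DAYS_PER_YEAR + 1), 24)
        if self.hour is None:
            self.hour = np.tile(np.arange(24), DAYS_PER_YEAR)
        for name in ("air_temp", "solar", "sky_temp", "substrate_temp", "wind"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (HOURS_PER_YEAR,):
                raise ValueError(f"{name} must have {HOURS_PER_YEAR} records, got {arr.shape}")
            setattr(self, name, arr)
        if (self.solar < 0).any():
            raise ValueError("negative solar irradiance")
        if (self.wind < 0).any():
            raise ValueError("negative wind speed")

    def record(self, i: int) -> EnvironmentHour:
        return EnvironmentHour(
            air_temp=float(self.air_temp[i]),
            solar=float(self.solar[i]),
            sky_temp=float(self.sky_temp[i]),
            substrate_temp=float(self.substrate_temp[i]),
            wind=float(self.wind[i]),
        )


def delta_offsets(fine: MonthlyClimate, coarse: MonthlyClimate) -> WarmOffsets:
    """Delta-method downscaling offsets: fine minus coarse monthly means."""
    return WarmOffsets(fine.tavg - coarse.tavg)


def apply_offsets(clim: MonthlyClimate, off: WarmOffsets) -> MonthlyClimate:
    """Add monthly warm offsets to the mean temperatures; DTR is unchanged."""
    return MonthlyClimate(tavg=clim.tavg + off.values, dtr=clim.dtr.copy())


def solar_declination(doy):
    """Solar declination (degrees) for day of year 1..365.

    delta = 23.45 sin(2 pi (284 + doy) / 365).
    """
    doy = np.asarray(doy)
    if ((doy < 1) | (doy > DAYS_PER_YEAR)).any():
        raise ValueError(f"day of year must be in 1..{DAYS_PER_YEAR}")
    out = 23.45 * np.sin(2.0 * np.pi * (284 + doy) / DAYS_PER_YEAR)
    return float(out) if out.ndim == 0 else out


def sunrise_hour(lat: float, doy) -> float:
    """Local solar hour of sunrise (0..12).

    Polar day clamps to 0 (sun never sets), polar night to 12 (never rises).
    """
    if abs(lat) > 90:
        raise ValueError("latitude out of range")
    delta = np.deg2rad(solar_declination(doy))
    phi = np.deg2rad(lat)
    x = -np.tan(phi) * np.tan(delta)
    # |x| > 1 has no sunrise: x < -1 is polar day, x > 1 polar night.
    h = 12.0 - np.degrees(np.arccos(np.clip(x, -1.0, 1.0))) / 15.0
    h = np.where(x <= -1.0, 0.0, np.where(x >= 1.0, 12.0, h))
    return float(h) if np.ndim(h) == 0 else h


def monthly_to_daily(clim: MonthlyClimate) -> tuple[np.ndarray, np.ndarray]:
    """Daily (Tmin, Tmax) series, length 365 each.

    The daily mean interpolates linearly between month midpoints (day 15 of
    each month), wrapping December to January; Tmin/Tmax sit half a diurnal
    range below/above the mean.
    """
    days = np.arange(1, DAYS_PER_YEAR + 1)
    knots = np.concatenate(
        ([MONTH_MIDPOINTS[-1] - DAYS_PER_YEAR], MONTH_MIDPOINTS, [MONTH_MIDPOINTS[0] + DAYS_PER_YEAR])
    )

    def _interp(vals: np.ndarray) -> np.ndarray:
        ext = np.concatenate(([vals[-1]], vals, [vals[0]]))
        return np.interp(days, knots, ext)

    mean = _interp(clim.tavg)
    dtr = _interp(clim.dtr)
    return mean - dtr / 2.0, mean + dtr / 2.0


def _day_length(h_sr) -> np.ndarray:
    return 2.0 * (12.0 - np.asarray(h_sr, dtype=float))


def _diurnal_curve(tmin, tmax, h_sr, day_length, hour):
    """Raw day/night interpolant (array-capable); see hourly_air_temperature."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    h_sr = np.asarray(h_sr, dtype=float)
    day_length = np.asarray(day_length, dtype=float)
    hour = np.asarray(hour, dtype=float)
    amp = tmax - tmin

    denom = day_length + 2.0 * DAY_LAG_HOURS
    with np.errstate(invalid="ignore", divide="ignore"):
        day_val = tmin + amp * np.sin(np.pi * (hour - h_sr) / denom)
        t_sunset = tmin + amp * np.sin(np.pi * day_length / denom)

        night_len = 24.0 - day_length
        since_sunset = np.mod(hour - (h_sr + day_length), 24.0)
        frac = np.where(night_len > 0, since_sunset / np.where(night_len > 0, night_len, 1.0), 0.0)
        eb = np.exp(-NIGHT_DECAY_SHAPE)
        shape = (np.exp(-NIGHT_DECAY_SHAPE * frac) - eb) / (1.0 - eb)
        night_val = tmin + (t_sunset - tmin) * shape

    is_day = (hour >= h_sr) & (hour <= h_sr + day_length)
    out = np.where(is_day, day_val, night_val)
    return out


def hourly_air_temperature(tmin: float, tmax: float, h_sr: float, day_length: float, hour: float) -> float:
    """Air temperature at a given local solar hour.

    Daytime (h_sr <= hour <= h_sr + day_length) follows a lagged sine from
    Tmin at sunrise, peaking DAY_LAG_HOURS-driven after solar noon; night
    cools exponentially (shape ``NIGHT_DECAY_SHAPE``) from the sunset value
    back down to Tmin at the following sunrise.
    """
    if tmax < tmin:
        raise ValueError(f"Tmax ({tmax}) < Tmin ({tmin})")
    return float(_diurnal_curve(tmin, tmax, h_sr, day_length, hour))


def _cos_zenith(lat, doy, hour):
    delta = np.deg2rad(solar_declination(doy))
    phi = np.deg2rad(np.asarray(lat, dtype=float))
    hour_angle = np.deg2rad(15.0 * (np.asarray(hour, dtype=float) - 12.0))
    return np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)


def clear_sky_irradiance(lat, doy, hour, elev):
    """Global horizontal clear-sky irradiance, W m^-2 (direct + diffuse).

    Beam attenuation follows Beer's law through an optical air mass scaled by
    the barometric pressure ratio at ``elev``; the diffuse term restores a
    fixed fraction of what the beam loses.
    """
    cosz = _cos_zenith(lat, doy, hour)
    pressure_ratio = np.exp(-np.asarray(elev, dtype=float) / PRESSURE_SCALE_HEIGHT_M)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        airmass = np.where(cosz > 0, pressure_ratio / np.where(cosz > 0, cosz, 1.0), np.inf)
        trans = ATMOSPHERIC_TRANSMITTANCE ** airmass
        direct = SOLAR_CONSTANT * trans * cosz
        diffuse = DIFFUSE_FRACTION * SOLAR_CONSTANT * (1.0 - trans) * cosz
        total = np.where(cosz > 0, direct + diffuse, 0.0)
    return float(total) if np.ndim(total) == 0 else total


def sky_substrate(ta, solar):
    """Effective sky and substrate surface temperatures (degC).

    Clear-sky atmospheric emissivity rises with air temperature
    (0.72 + 0.005 Ta, clamped to (0, 1]); the substrate runs hotter than the
    air in proportion to absorbed shortwave.
    """
    ta = np.asarray(ta, dtype=float)
    solar = np.asarray(solar, dtype=float)
    eps = np.clip(0.72 + 0.005 * ta, 1e-3, 1.0)
    sky = eps ** 0.25 * (ta + 273.15) - 273.15
    sub = ta + solar * SUBSTRATE_SOLAR_COEFF
    if np.ndim(sky) == 0:
        return float(sky), float(sub)
    return sky, sub


def build_hourly_environment(
    site,
    scenario: str,
    wind: float = 1.0,
    preserve_daily_mean: bool = True,
) -> HourlyEnvironment:
    """Compose the full 8760-hour environment for one site and scenario.

    ``site`` is a SiteCell carrying a ``climate`` mapping scenario label ->
    MonthlyClimate. Wind is constant. With ``preserve_daily_mean`` (default)
    each day's 24-h air-temperature curve is shifted by a constant so its
    mean equals the interpolated daily mean: the raw day/night interpolant
    runs systematically cool (by roughly 5-10% of the diurnal range), and the
    correction removes that bias without affecting continuity, periodicity,
    or the exact linearity of the series in the monthly means.
    """
    try:
        clim = site.climate[scenario]
    except KeyError:
        raise KeyError(
            f"site {site.site_id!r} has no climate for scenario {scenario!r}"
        ) from None
    if wind < 0:
        raise ValueError("wind must be non-negative")

    lat = site.latitude
    elev = site.elevation
    days = np.arange(1, DAYS_PER_YEAR + 1)
    h_sr = np.atleast_1d(sunrise_hour(lat, days))
    day_len = _day_length(h_sr)
    tmin, tmax = monthly_to_daily(clim)

    hours = np.arange(24, dtype=float)
    air = _diurnal_curve(
        tmin[:, None], tmax[:, None], h_sr[:, None], day_len[:, None], hours[None, :]
    )
    if preserve_daily_mean:
        target = (tmin + tmax) / 2.0
        air = air + (target - air.mean(axis=1))[:, None]

    solar = clear_sky_irradiance(lat, days[:, None], hours[None, :], elev)
    sky, sub = sky_substrate(air, solar)

    return HourlyEnvironment(
        air_temp=air.ravel(),
        solar=np.maximum(solar, 0.0).ravel(),
        sky_temp=np.asarray(sky).ravel(),
        substrate_temp=np.asarray(sub).ravel(),
        wind=np.full(HOURS_PER_YEAR, float(wind)),
    )
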