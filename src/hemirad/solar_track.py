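"""Solar position, annual solar track, and direct-beam transmissivity.

Solar positions follow the NOAA solar calculator parameterisation (Julian
century → solar declination and equation of time → true solar time → hour
angle → zenith/azimuth).  A point's track is computed at 2-minute cadence
over the annual cycle in fixed-offset UTC+1 civil time and the resulting
direct-beam transmissivity (DBT) is averaged to hourly steps — 8784 for
the leap year 2020.

DBT at one instant is the sky fraction of the hemispheric image over the
solar disc (apparent diameter 0.53°).  Because the disc is smaller than a
1° image cell, the disc is supersampled with a fixed sub-grid of
directions; sub-samples falling below the astronomical horizon carry no
image pixel and are excluded from the ratio, so an unobstructed flat scene
has DBT exactly 1 for any solar zenith < 90° and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .terrain_horizon import HemisphericImage

__all__ = [
    "SolarPosition",
    "TransmissivitySeries",
    "solar_position",
    "solar_track",
    "dbt_at_position",
    "dbt_series",
    "hourly_average",
]


@dataclass(frozen=True)
class SolarPosition:
    """Sun direction at one instant; zenith > 90° means the sun is down."""

    zenith: float
    azimuth: float
    timestamp: pd.Timestamp


@dataclass
class TransmissivitySeries:
    """Direct-beam transmissivity fractions on a regular time grid.

    Timestamps are naive, fixed-offset UTC+1 (CET) and mark the *start* of
    each step's averaging period.
    """

    values: np.ndarray
    timestamps: pd.DatetimeIndex
    cadence_minutes: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.timestamps),):
            raise ValueError("values and timestamps differ in length")
        valid = ~np.isnan(self.values)
        if np.any((self.values[valid] < 0) | (self.values[valid] > 1)):
            raise ValueError("transmissivity values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# NOAA solar position


def _noaa_angles(times_utc_days: np.ndarray, lat: float, lon: float,
                 frac_of_day: np.ndarray, tz_hours: float,
                 apply_refraction: bool = False):
    """Vectorised NOAA solar-calculator equations.

    ``times_utc_days`` are Julian days; ``frac_of_day`` is local civil time
    past midnight as a day fraction.  Returns (zenith, azimuth) in degrees.
    """
    jc = (times_utc_days - 2451545.0) / 36525.0
    l0 = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = np.radians(m)
    c = (np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
         + np.sin(3 * mrad) * 0.000289)
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obliq_rad = np.radians(obliq)
    decl = np.arcsin(np.sin(obliq_rad) * np.sin(np.radians(app_long)))
    var_y = np.tan(obliq_rad / 2.0) ** 2
    l0rad = np.radians(l0)
    eqtime = 4.0 * np.degrees(
        var_y * np.sin(2 * l0rad)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * var_y * np.sin(mrad) * np.cos(2 * l0rad)
        - 0.5 * var_y ** 2 * np.sin(4 * l0rad)
        - 1.25 * ecc ** 2 * np.sin(2 * mrad)
    )
    tst = np.mod(frac_of_day * 1440.0 + eqtime + 4.0 * lon - 60.0 * tz_hours, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)
    lat_r = np.radians(lat)
    ha_r = np.radians(ha)
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha_r))
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    zen_r = np.radians(zen)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = ((np.sin(lat_r) * np.cos(zen_r)) - np.sin(decl)) / (np.cos(lat_r) * np.sin(zen_r))
    az_acos = np.degrees(np.arccos(np.clip(cos_az, -1.0, 1.0)))
    azim = np.where(ha > 0.0, np.mod(az_acos + 180.0, 360.0), np.mod(540.0 - az_acos, 360.0))
    azim = np.where(np.isfinite(azim), azim, 0.0)  # sun at exact zenith/nadir
    if apply_refraction:
        elev = 90.0 - zen
        elev_r = np.radians(elev)
        with np.errstate(divide="ignore", invalid="ignore"):
            refr = np.where(
                elev > 85.0, 0.0,
                np.where(
                    elev > 5.0,
                    (58.1 / np.tan(elev_r) - 0.07 / np.tan(elev_r) ** 3
                     + 0.000086 / np.tan(elev_r) ** 5),
                    np.where(
                        elev > -0.575,
                        1735.0 + elev * (-518.2 + elev * (103.4 + elev * (-12.79 + elev * 0.711))),
                        -20.772 / np.tan(elev_r),
                    ),
                ),
            ) / 3600.0
        zen = zen - refr
    return zen, azim


def _julian_day(times: pd.DatetimeIndex, tz_hours: float) -> np.ndarray:
    """Julian day of naive local timestamps with a fixed UTC offset."""
    utc = times - pd.Timedelta(hours=tz_hours)
    # Julian day of the Unix epoch is 2440587.5
    return utc.asi8 / 86_400_000_000_000.0 + 2440587.5


def solar_position(timestamp, latitude: float, longitude: float,
                   tz_hours: float = 1.0,
                   apply_refraction: bool = False) -> SolarPosition:
    """NOAA solar position for one naive local (fixed UTC-offset) timestamp."""
    ts = pd.Timestamp(timestamp)
    idx = pd.DatetimeIndex([ts])
    jd = _julian_day(idx, tz_hours)
    frac = np.array([(ts - ts.normalize()).total_seconds() / 86400.0])
    zen, az = _noaa_angles(jd, latitude, longitude, frac, tz_hours, apply_refraction)
    return SolarPosition(zenith=float(zen[0]), azimuth=float(az[0]), timestamp=ts)


def solar_track(year: int, latitude: float, longitude: float,
                step_minutes: int = 2, tz_hours: float = 1.0,
                apply_refraction: bool = False):
    """Solar positions for every step of a calendar year.

    Returns (timestamps, zenith array, azimuth array); timestamps run from
    1 Jan 00:00 to 31 Dec 24:00 − step in naive UTC+offset civil time.
    """
    if 60 % step_minutes != 0:
        raise ValueError("step must divide 60 minutes")
    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=1)
    times = pd.date_range(start, end, freq=f"{step_minutes}min", inclusive="left")
    jd = _julian_day(times, tz_hours)
    frac = ((times - times.normalize()).total_seconds() / 86400.0).to_numpy()
    zen, az = _noaa_angles(jd, latitude, longitude, frac, tz_hours, apply_refraction)
    return times, zen, az


def positions_for_times(times: pd.DatetimeIndex, latitude: float,
                        longitude: float, tz_hours: float = 1.0,
                        apply_refraction: bool = False):
    """Zenith/azimuth arrays for an arbitrary naive local time index."""
    jd = _julian_day(times, tz_hours)
    frac = ((times - times.normalize()).total_seconds() / 86400.0).to_numpy()
    return _noaa_angles(jd, latitude, longitude, frac, tz_hours, apply_refraction)


# ---------------------------------------------------------------------------
# solar-disc DBT


def _disc_offsets(n: int = 13) -> np.ndarray:
    """Unit-disc sample offsets: an n×n grid clipped to the disc."""
    u = np.linspace(-1.0, 1.0, n)
    uu, vv = np.meshgrid(u, u)
    keep = uu ** 2 + vv ** 2 <= 1.0 + 1e-12
    return np.column_stack([uu[keep], vv[keep]])


_DISC = _disc_offsets()


def _disc_directions(zenith, azimuth, radius_deg: float):
    """(zenith', azimuth') of disc sub-samples around sun directions.

    ``zenith``/``azimuth`` may be arrays of shape (n,); the result has
    shape (n, n_samples).
    """
    zen = np.atleast_1d(np.asarray(zenith, dtype=float))
    azi = np.atleast_1d(np.asarray(azimuth, dtype=float))
    zr = np.radians(zen)[:, None]
    ar = np.radians(azi)[:, None]
    r = np.radians(radius_deg)
    # sun direction and orthonormal tangent frame (x = east, y = north, z = up)
    sz, cz = np.sin(zr), np.cos(zr)
    sa, ca = np.sin(ar), np.cos(ar)
    n_vec = np.stack([sz * sa, sz * ca, cz], axis=-1)          # (n,1,3)
    e1 = np.stack([cz * sa, cz * ca, -sz], axis=-1)            # towards horizon
    e2 = np.stack([ca, -sa, np.zeros_like(ca)], axis=-1)       # along horizon
    du = (_DISC[None, :, 0] * r)[..., None]
    dv = (_DISC[None, :, 1] * r)[..., None]
    v = n_vec + du * e1 + dv * e2
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    zen_s = np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))
    az_s = np.degrees(np.arctan2(v[..., 0], v[..., 1])) % 360.0
    return zen_s, az_s


def dbt_at_position(image: HemisphericImage, sun: SolarPosition,
                    config: ModelConfig | None = None) -> float:
    """Sky fraction of the image over the solar disc; 0 with the sun down."""
    config = config or ModelConfig()
    if sun.zenith >= 90.0:
        return 0.0
    zen_s, az_s = _disc_directions(sun.zenith, sun.azimuth,
                                   config.solar_disc_diameter / 2.0)
    return float(_disc_sky_fraction(image, zen_s, az_s)[0])


def _disc_sky_fraction(image: HemisphericImage, zen_s: np.ndarray,
                       az_s: np.ndarray) -> np.ndarray:
    """Mean sky membership over disc sub-samples (axis -1), excluding
    sub-samples below the astronomical horizon."""
    valid = zen_s < 90.0
    zi = np.clip((zen_s / image.zenith_step).astype(int), 0, image.sky.shape[0] - 1)
    ai = (az_s / image.azimuth_step).astype(int) % image.sky.shape[1]
    sky = image.sky[zi, ai] & valid
    n_valid = valid.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = sky.sum(axis=-1) / n_valid
    return np.where(n_valid == 0, 0.0, frac)


def dbt_series(image: HemisphericImage, times: pd.DatetimeIndex,
               zenith: np.ndarray, azimuth: np.ndarray,
               config: ModelConfig | None = None,
               chunk: int = 4096) -> TransmissivitySeries:
    """DBT for a whole solar track against one hemispheric image."""
    config = config or ModelConfig()
    zenith = np.asarray(zenith, dtype=float)
    azimuth = np.asarray(azimuth, dtype=float)
    out = np.zeros(zenith.shape)
    up = np.flatnonzero(zenith < 90.0)
    radius = config.solar_disc_diameter / 2.0
    for start in range(0, up.size, chunk):
        sel = up[start:start + chunk]
        zs, as_ = _disc_directions(zenith[sel], azimuth[sel], radius)
        out[sel] = _disc_sky_fraction(image, zs, as_)
    step = np.diff(times.asi8).min() / 60_000_000_000.0 if len(times) > 1 else np.nan
    return TransmissivitySeries(out, times, float(step))


def hourly_average(fine: TransmissivitySeries) -> TransmissivitySeries:
    """Average a sub-hourly series to hourly steps (timestamp = hour start)."""
    cad = fine.cadence_minutes
    if not cad or 60.0 % cad != 0.0:
        raise ValueError(f"cadence {cad} min does not divide 60")
    per_hour = round(60.0 / cad)
    n = fine.values.size
    if n % per_hour != 0:
        raise ValueError("series is not an integer number of hours")
    first = fine.timestamps[0]
    if first.minute != 0 or first.second != 0:
        raise ValueError("series must start on an hour boundary")
    values = fine.values.reshape(-1, per_hour).mean(axis=1)
    hours = fine.timestamps[::per_hour]
    return TransmissivitySeries(values, hours, 60.0)
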