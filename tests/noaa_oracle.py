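"""Independent scalar implementation of the NOAA solar-calculator equations.

Written cell-by-cell from the NOAA spreadsheet layout with plain ``math``
and its own Julian-day computation, as an oracle for the vectorised
implementation in ``hemirad.solar_track``.
"""

from __future__ import annotations

import math


def julian_day(year: int, month: int, day: int, day_fraction_utc: float) -> float:
    """Julian day from a Gregorian calendar date and UTC day fraction."""
    jd0 = (367 * year
           - (7 * (year + (month + 9) // 12)) // 4
           + (275 * month) // 9
           + day + 1721013.5)
    return jd0 + day_fraction_utc


def solar_zenith_azimuth(year: int, month: int, day: int,
                         local_hours: float, latitude: float,
                         longitude: float, tz_hours: float = 1.0):
    """(zenith, azimuth) in degrees for one local civil instant."""
    frac_local = local_hours / 24.0
    jd = julian_day(year, month, day, frac_local - tz_hours / 24.0)
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eccent = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_of_centre = (math.sin(math.radians(geom_mean_anom))
                    * (1.914602 - jc * (0.004817 + 0.000014 * jc))
                    + math.sin(math.radians(2 * geom_mean_anom))
                    * (0.019993 - 0.000101 * jc)
                    + math.sin(math.radians(3 * geom_mean_anom)) * 0.000289)
    true_long = geom_mean_long + eq_of_centre
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    declination = math.degrees(math.asin(
        math.sin(math.radians(obliq_corr)) * math.sin(math.radians(app_long))))

    var_y = math.tan(math.radians(obliq_corr / 2.0)) ** 2
    eq_of_time = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(geom_mean_long))
        - 2.0 * eccent * math.sin(math.radians(geom_mean_anom))
        + 4.0 * eccent * var_y * math.sin(math.radians(geom_mean_anom))
        * math.cos(2.0 * math.radians(geom_mean_long))
        - 0.5 * var_y * var_y * math.sin(4.0 * math.radians(geom_mean_long))
        - 1.25 * eccent * eccent * math.sin(2.0 * math.radians(geom_mean_anom)))

    true_solar_time = (local_hours * 60.0 + eq_of_time + 4.0 * longitude
                       - 60.0 * tz_hours) % 1440.0
    if true_solar_time / 4.0 < 0.0:
        hour_angle = true_solar_time / 4.0 + 180.0
    else:
        hour_angle = true_solar_time / 4.0 - 180.0

    lat_r = math.radians(latitude)
    decl_r = math.radians(declination)
    cos_zen = (math.sin(lat_r) * math.sin(decl_r)
               + math.cos(lat_r) * math.cos(decl_r) * math.cos(math.radians(hour_angle)))
    zenith = math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))

    denom = math.cos(lat_r) * math.sin(math.radians(zenith))
    if abs(denom) < 1e-12:
        return zenith, 0.0
    cos_az = (math.sin(lat_r) * math.cos(math.radians(zenith)) - math.sin(decl_r)) / denom
    az_acos = math.degrees(math.acos(max(-1.0, min(1.0, cos_az))))
    if hour_angle > 0.0:
        azimuth = (az_acos + 180.0) % 360.0
    else:
        azimuth = (540.0 - az_acos) % 360.0
    return zenith, azimuth
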