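"""Projected → geographic coordinate conversion for solar geometry.

Solar position needs latitude/longitude, but the model grids live in a
projected metric CRS.  Two conversions are supported:

* EPSG:2056 (Swiss LV95): the swisstopo approximate polynomial inverse,
  accurate to ~1 m over Switzerland — far below the <0.01° solar-position
  tolerance.
* Any other CRS: a local equirectangular anchor.  The caller registers the
  geographic coordinates of a reference projected point once; metric offsets
  are then converted with the local metres-per-degree scale.  Adequate for
  the desk-scale synthetic scenes this package generates (errors < 1e-4°
  per km of offset at mid-latitudes).
"""

from __future__ import annotations

import math

__all__ = ["lv95_to_wgs84", "LocalAnchor", "to_latlon"]

EPSG_LV95 = 2056
_GEOGRAPHIC_EPSG = {4326, 4258, 4617, 4269}


def lv95_to_wgs84(e: float, n: float) -> tuple[float, float]:
    """Swiss LV95 (EPSG:2056) easting/northing → (lat, lon) in degrees.

    swisstopo's approximate series expansion about Bern; ~1 m accuracy.
    """
    y = (e - 2_600_000.0) / 1_000_000.0
    x = (n - 1_200_000.0) / 1_000_000.0
    lon = (2.6779094
           + 4.728982 * y
           + 0.791484 * y * x
           + 0.1306 * y * x * x
           - 0.0436 * y * y * y)
    lat = (16.9023892
           + 3.238272 * x
           - 0.270978 * y * y
           - 0.002528 * x * x
           - 0.0447 * y * y * x
           - 0.0140 * x * x * x)
    # the series yields units of 10^4 seconds of arc
    return lat * 100.0 / 36.0, lon * 100.0 / 36.0


class LocalAnchor:
    """Equirectangular mapping between a projected CRS and geographic space.

    Anchored at one projected point with known (lat, lon); offsets in metres
    are scaled by the metres-per-degree of latitude/longitude at the anchor.
    """

    EARTH_RADIUS = 6_371_000.0  # m, mean

    def __init__(self, x0: float, y0: float, lat0: float, lon0: float):
        self.x0, self.y0 = float(x0), float(y0)
        self.lat0, self.lon0 = float(lat0), float(lon0)
        self._m_per_deg_lat = math.pi / 180.0 * self.EARTH_RADIUS
        self._m_per_deg_lon = self._m_per_deg_lat * math.cos(math.radians(lat0))

    def to_latlon(self, x: float, y: float) -> tuple[float, float]:
        lat = self.lat0 + (y - self.y0) / self._m_per_deg_lat
        lon = self.lon0 + (x - self.x0) / self._m_per_deg_lon
        return lat, lon


def to_latlon(x: float, y: float, crs_epsg: int,
              anchor: LocalAnchor | None = None) -> tuple[float, float]:
    """Convert projected coordinates to (lat, lon) degrees.

    EPSG:2056 uses the built-in polynomial inverse; any other projected CRS
    requires a :class:`LocalAnchor`.
    """
    if crs_epsg in _GEOGRAPHIC_EPSG:
        raise ValueError(f"EPSG:{crs_epsg} is geographic; model grids must be projected")
    if crs_epsg == EPSG_LV95:
        return lv95_to_wgs84(x, y)
    if anchor is None:
        raise ValueError(
            f"no geographic anchor registered for EPSG:{crs_epsg}; "
            "provide a LocalAnchor with the lat/lon of a reference point"
        )
    return anchor.to_latlon(x, y)
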