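"""Terrain horizon lines and terrain-only synthetic hemispheric images.

The terrain stage computes, for each 1° azimuth, the maximum elevation angle
of the terrain surface seen from a viewpoint, out to a search radius.  Two
stages are run in practice — a local high-resolution stage (5 m DTM, 300 m
radius) resolving between-point differences, and a regional coarse stage
(50 m DTM, 25 km radius) capturing distant topography — and combined by a
per-azimuth maximum.  The combined horizon thresholds a (zenith, azimuth)
grid into the binary sky/obstructed hemispheric image.

Conventions: azimuth is degrees clockwise from north, bin k covering
[k, k+1)° with its centre at k+0.5°; zenith bins likewise with centres at
0.5°, …, 89.5°.  Rendered images are south-up / east-right, matching how
upward-looking fisheye photographs are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ModelConfig
from .grids import ElevationGrid

__all__ = [
    "HorizonProfile",
    "HemisphericImage",
    "horizon_from_grid",
    "combine_horizons",
    "horizon_to_image",
]


@dataclass
class HorizonProfile:
    """Per-azimuth terrain elevation angles (degrees above horizontal).

    ``angles[k]`` belongs to the azimuth bin [k·step, (k+1)·step) degrees
    clockwise from north.  Angles may be negative (viewer above terrain);
    they are floored at zero only when thresholding into an image.
    """

    angles: np.ndarray
    azimuth_step: float = 1.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        n = round(360.0 / self.azimuth_step)
        if self.angles.shape != (n,):
            raise ValueError(f"expected {n} azimuth bins, got {self.angles.shape}")
        if np.any(np.abs(self.angles) > 90.0 + 1e-9):
            raise ValueError("horizon angles must lie in [-90, 90] degrees")

    @property
    def azimuths(self) -> np.ndarray:
        """Bin-centre azimuths in degrees."""
        n = self.angles.size
        return (np.arange(n) + 0.5) * self.azimuth_step


@dataclass
class HemisphericImage:
    """Binary sky map over the upper hemisphere on a (zenith, azimuth) grid.

    ``sky[i, j]`` is True where the direction with zenith bin i and azimuth
    bin j is unobstructed.  Bin centres follow the module conventions above.
    """

    sky: np.ndarray
    zenith_step: float = 1.0
    azimuth_step: float = 1.0
    orientation: str = field(default="south-up,east-right", repr=False)

    def __post_init__(self) -> None:
        self.sky = np.asarray(self.sky, dtype=bool)
        nz = round(90.0 / self.zenith_step)
        na = round(360.0 / self.azimuth_step)
        if self.sky.shape != (nz, na):
            raise ValueError(f"expected image shape {(nz, na)}, got {self.sky.shape}")

    @property
    def zenith_centres(self) -> np.ndarray:
        return (np.arange(self.sky.shape[0]) + 0.5) * self.zenith_step

    @property
    def azimuth_centres(self) -> np.ndarray:
        return (np.arange(self.sky.shape[1]) + 0.5) * self.azimuth_step

    def sky_fraction(self) -> float:
        """Unweighted fraction of sky cells (diagnostic, not an SVF)."""
        return float(self.sky.mean())

    def render_polar(self, size: int = 181) -> np.ndarray:
        """Render as a south-up, east-right polar raster for inspection.

        Returns a float array in [0, 1] (1 = sky, 0 = obstructed, NaN
        outside the hemisphere disc); purely a debug aid.
        """
        half = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        dx = (xx - half) / half   # +x → right
        dy = (yy - half) / half   # +y → down
        r = np.hypot(dx, dy)
        zen = r * 90.0
        # south-up, east-right: up on the page is azimuth 180°, right is 90°
        az = (180.0 - np.degrees(np.arctan2(dx, -dy))) % 360.0
        out = np.full((size, size), np.nan)
        inside = zen < 90.0
        zi = np.minimum((zen[inside] / self.zenith_step).astype(int), self.sky.shape[0] - 1)
        ai = (az[inside] / self.azimuth_step).astype(int) % self.sky.shape[1]
        out[inside] = self.sky[zi, ai].astype(float)
        return out


def _bilinear(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sample with NaN outside the grid."""
    return ndimage.map_coordinates(values, [rows, cols], order=1,
                                   mode="constant", cval=np.nan)


def horizon_from_grid(dtm: ElevationGrid, point: tuple[float, float],
                      radius: float, azimuth_step: float = 1.0,
                      viewer_height: float = 0.0) -> HorizonProfile:
    """Horizon profile around ``point`` from a single elevation grid.

    Each azimuth ray is sampled at half-cell intervals out to ``radius``
    with bilinear elevation interpolation; the profile records the maximum
    of atan((z - z_viewer) / distance) along the ray.  If the grid holds no
    data around the point the profile is all-NaN, signalling the caller to
    fall back to another (e.g. regional-only) stage.
    """
    x0, y0 = float(point[0]), float(point[1])
    if not dtm.contains(x0, y0):
        raise ValueError(f"point {point} lies outside the elevation grid {dtm.bounds}")
    if radius < dtm.resolution:
        raise ValueError(f"radius {radius} m is smaller than one grid cell ({dtm.resolution} m)")

    r0, c0 = dtm.world_to_index(x0, y0)
    z_ground = _bilinear(dtm.values, np.atleast_1d(r0), np.atleast_1d(c0))[0]
    n_az = round(360.0 / azimuth_step)
    if np.isnan(z_ground):
        return HorizonProfile(np.full(n_az, np.nan), azimuth_step)
    z_view = z_ground + viewer_height

    step = dtm.resolution / 2.0
    dists = np.arange(step, radius + step / 2.0, step)          # (nd,)
    az = np.radians((np.arange(n_az) + 0.5) * azimuth_step)     # bin centres
    # clockwise from north: north = +y, east = +x
    dx = np.sin(az)[:, None] * dists[None, :]
    dy = np.cos(az)[:, None] * dists[None, :]
    rows, cols = dtm.world_to_index(x0 + dx, y0 + dy)
    z = _bilinear(dtm.values, rows.ravel(), cols.ravel()).reshape(n_az, dists.size)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(z - z_view, dists[None, :]))
    ang[np.isnan(z)] = -90.0
    angles = ang.max(axis=1)
    angles[np.all(np.isnan(z), axis=1)] = np.nan
    return HorizonProfile(angles, azimuth_step)


def combine_horizons(local: HorizonProfile, regional: HorizonProfile) -> HorizonProfile:
    """Per-azimuth maximum of two horizon profiles.

    NaN stages (nodata neighbourhoods) defer to the other stage, so a
    point with no local DTM coverage falls back to the regional horizon.
    """
    if local.angles.shape != regional.angles.shape:
        raise ValueError("horizon profiles differ in length")
    if local.azimuth_step != regional.azimuth_step:
        raise ValueError("horizon profiles differ in azimuth convention")
    combined = np.fmax(local.angles, regional.angles)
    return HorizonProfile(combined, local.azimuth_step)


def horizon_to_image(horizon: HorizonProfile,
                     config: ModelConfig | None = None) -> HemisphericImage:
    """Threshold a horizon profile into a terrain-only hemispheric image.

    A cell is sky iff its elevation angle (90° − zenith centre) exceeds the
    horizon angle of its azimuth; negative horizon angles are floored at
    zero (terrain below the horizontal plane cannot open sky beyond the
    astronomical horizon in the image).
    """
    config = config or ModelConfig()
    zen_step = config.zenith_step
    nz = config.n_zenith
    elev = 90.0 - (np.arange(nz) + 0.5) * zen_step            # per zenith row
    h = np.maximum(np.nan_to_num(horizon.angles, nan=0.0), 0.0)
    sky = elev[:, None] > h[None, :]
    return HemisphericImage(sky, zen_step, horizon.azimuth_step)
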