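"""Parametric test scenes with closed-form geometry and a ray-marching oracle.

Every fixture is analytic-first: terrain surfaces and crown footprints are
defined as closed-form functions of (x, y), and the rasters consumed by the
model are *samples* of those functions.  The dense ray-marching oracle
(`oracle_visibility`, 0.1 m steps against the analytic scene) is therefore
independent of any raster interpolation choice and serves as ground truth
for horizon angles and canopy path lengths.

Scenes are placed in the Swiss LV95 projected CRS (EPSG:2056) at plausible
coordinates so that solar geometry works without extra configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .grids import CanopyHeightGrid, ElevationGrid, ForestMask, MixRateGrid

__all__ = ["SceneSpec", "Scene", "make_scene", "make_terrain", "make_forest",
           "oracle_visibility", "oracle_horizon"]

TERRAIN_KINDS = ("flat", "inclined_plane", "crater", "gaussian_hills")
FOREST_KINDS = ("none", "single_crown", "plantation", "uniform_slab", "gapped")
FOREST_EDGE_BUFFER = 25.0  # m


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic terrain/forest fixture."""

    terrain_kind: str = "flat"
    forest_kind: str = "none"
    extent: float = 200.0            # m, square scene side
    base_elevation: float = 1000.0   # m a.s.l.
    slope_deg: float = 10.0          # inclined plane (rising northwards)
    rim_angle_deg: float = 30.0      # crater rim elevation angle from centre
    crater_radius: float = 80.0      # m
    hill_amplitude: float = 30.0     # m, gaussian hills
    hill_count: int = 4
    crown_height: float = 15.0       # m
    crown_width: float = 2.0         # m, square footprint side
    crown_offset: tuple[float, float] = (0.0, 5.0)  # single crown, (east, north) of centre
    spacing: float = 5.0             # m, plantation lattice
    slab_height: float = 20.0        # m, uniform slab
    crown_density: float = 0.02      # crowns per m², gapped forest
    evergreen_fraction: float = 1.0  # constant mix rate
    origin_x: float = 2_650_000.0    # LV95 easting of the west edge
    origin_y: float = 1_180_000.0    # LV95 northing of the north edge
    local_resolution: float = 5.0    # m, local DTM
    regional_resolution: float = 50.0  # m, regional DTM
    chm_resolution: float = 1.0      # m
    coarse_resolution: float = 10.0  # m, mix rate / mask
    seed: int = 0

    def __post_init__(self) -> None:
        if self.terrain_kind not in TERRAIN_KINDS:
            raise ValueError(f"unknown terrain kind {self.terrain_kind!r}")
        if self.forest_kind not in FOREST_KINDS:
            raise ValueError(f"unknown forest kind {self.forest_kind!r}")
        if self.extent <= 2 * self.local_resolution:
            raise ValueError("scene extent is degenerate")

    @property
    def centre(self) -> tuple[float, float]:
        return (self.origin_x + self.extent / 2.0,
                self.origin_y - self.extent / 2.0)


class Scene:
    """Closed-form scene geometry plus raster sampling."""

    def __init__(self, spec: SceneSpec):
        self.spec = spec

    # -- analytic surfaces ------------------------------------------------

    def terrain_elevation(self, x, y):
        """Closed-form terrain height at world coordinates."""
        s = self.spec
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy = s.centre
        if s.terrain_kind == "flat":
            return np.broadcast_to(np.float64(s.base_elevation), x.shape).copy()
        if s.terrain_kind == "inclined_plane":
            return s.base_elevation + (y - cy) * np.tan(np.radians(s.slope_deg))
        if s.terrain_kind == "crater":
            # cone rising from the centre at the rim angle, capped at the rim
            r = np.hypot(x - cx, y - cy)
            rise = np.minimum(r, s.crater_radius) * np.tan(np.radians(s.rim_angle_deg))
            return s.base_elevation + rise
        if s.terrain_kind == "gaussian_hills":
            z = np.full(x.shape, float(s.base_elevation))
            for hx, hy, amp, sig in self._hills:
                z = z + amp * np.exp(-((x - hx) ** 2 + (y - hy) ** 2) / (2 * sig ** 2))
            return z
        raise AssertionError(s.terrain_kind)

    @cached_property
    def _hills(self):
        s = self.spec
        rng = np.random.default_rng(np.random.SeedSequence([s.seed, 1]))
        hills = []
        for _ in range(s.hill_count):
            hx = s.origin_x + rng.uniform(0.2, 0.8) * s.extent
            hy = s.origin_y - rng.uniform(0.2, 0.8) * s.extent
            amp = rng.uniform(0.5, 1.0) * s.hill_amplitude
            sig = rng.uniform(0.05, 0.15) * s.extent
            hills.append((hx, hy, amp, sig))
        return hills

    @cached_property
    def crowns(self) -> list[tuple[float, float, float, float]]:
        """Square crowns as (centre_x, centre_y, half_width, height)."""
        s = self.spec
        cx, cy = s.centre
        if s.forest_kind in ("none", "uniform_slab"):
            return []
        if s.forest_kind == "single_crown":
            return [(cx + s.crown_offset[0], cy + s.crown_offset[1],
                     s.crown_width / 2.0, s.crown_height)]
        if s.forest_kind == "plantation":
            n = int(s.extent // s.spacing)
            crowns = []
            for i in range(n):
                for j in range(n):
                    crowns.append((s.origin_x + (i + 0.5) * s.spacing,
                                   s.origin_y - (j + 0.5) * s.spacing,
                                   s.crown_width / 2.0, s.crown_height))
            return crowns
        if s.forest_kind == "gapped":
            # seeded uniform placement, snapped to whole metres so crown
            # footprints are exactly representable on the 1 m canopy raster
            rng = np.random.default_rng(np.random.SeedSequence([s.seed, 2]))
            count = max(int(s.crown_density * s.extent ** 2), 1)
            half = s.crown_width / 2.0
            lo, hi = int(np.ceil(half)), int(s.extent - np.ceil(half))
            xs = s.origin_x + rng.integers(lo, hi + 1, count)
            ys = s.origin_y - rng.integers(lo, hi + 1, count)
            return [(float(x), float(y), half, s.crown_height) for x, y in zip(xs, ys)]
        raise AssertionError(s.forest_kind)

    def canopy_height(self, x, y):
        """Closed-form canopy height above ground at world coordinates."""
        s = self.spec
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if s.forest_kind == "none":
            return np.zeros(x.shape)
        if s.forest_kind == "uniform_slab":
            # the slab ends at the scene boundary, like its rasterisation
            inside = ((x >= s.origin_x) & (x <= s.origin_x + s.extent)
                      & (y <= s.origin_y) & (y >= s.origin_y - s.extent))
            return np.where(inside, float(s.slab_height), 0.0)
        h = np.zeros(x.shape)
        for ccx, ccy, half, height in self.crowns:
            inside = (np.abs(x - ccx) <= half) & (np.abs(y - ccy) <= half)
            h = np.where(inside, np.maximum(h, height), h)
        return h

    # -- raster sampling --------------------------------------------------

    def _grid_coords(self, resolution: float, pad: float = 0.0):
        s = self.spec
        n = int(round((s.extent + 2 * pad) / resolution))
        cols = np.arange(n)
        x = s.origin_x - pad + (cols + 0.5) * resolution
        y = s.origin_y + pad - (cols + 0.5) * resolution
        return np.meshgrid(x, y), (s.origin_x - pad, s.origin_y + pad)

    def terrain_grids(self) -> tuple[ElevationGrid, ElevationGrid]:
        """Local and regional DTM rasters sampled from the analytic surface."""
        s = self.spec
        (xx, yy), origin = self._grid_coords(s.local_resolution)
        local = ElevationGrid(values=self.terrain_elevation(xx, yy),
                              resolution=s.local_resolution, origin=origin)
        (xx, yy), origin = self._grid_coords(s.regional_resolution)
        regional = ElevationGrid(values=self.terrain_elevation(xx, yy),
                                 resolution=s.regional_resolution, origin=origin)
        return local, regional

    def forest_grids(self) -> tuple[CanopyHeightGrid, MixRateGrid, ForestMask]:
        """CHM (1 m), mix rate and forest mask (10 m, with 25 m edge buffer)."""
        s = self.spec
        (xx, yy), origin = self._grid_coords(s.chm_resolution)
        chm_values = self.canopy_height(xx, yy)
        chm = CanopyHeightGrid(values=chm_values, resolution=s.chm_resolution,
                               origin=origin)

        (cxx, cyy), corigin = self._grid_coords(s.coarse_resolution)
        mix = MixRateGrid(values=np.full(cxx.shape, float(s.evergreen_fraction)),
                          resolution=s.coarse_resolution, origin=corigin)

        # forest mask: code 1 within the edge buffer of any canopy, else 2
        codes = np.full(cxx.shape, 2, dtype=np.int16)
        if chm_values.any():
            canopy_x = xx[chm_values > 0]
            canopy_y = yy[chm_values > 0]
            for idx in np.ndindex(cxx.shape):
                d2 = (canopy_x - cxx[idx]) ** 2 + (canopy_y - cyy[idx]) ** 2
                if d2.min() <= FOREST_EDGE_BUFFER ** 2:
                    codes[idx] = 1
        mask = ForestMask(values=codes, resolution=s.coarse_resolution, origin=corigin)
        return chm, mix, mask


def make_scene(spec: SceneSpec) -> Scene:
    return Scene(spec)


def make_terrain(spec: SceneSpec) -> tuple[ElevationGrid, ElevationGrid]:
    """Local and regional elevation rasters for a scene spec."""
    return Scene(spec).terrain_grids()


def make_forest(spec: SceneSpec) -> tuple[CanopyHeightGrid, MixRateGrid, ForestMask]:
    """Canopy height, mix-rate and forest-mask rasters for a scene spec."""
    return Scene(spec).forest_grids()


# ---------------------------------------------------------------------------
# dense ray-marching oracle


def oracle_visibility(scene: Scene | SceneSpec, point: tuple[float, float],
                      zenith_deg: float, azimuth_deg: float,
                      max_range: float = 300.0, step: float = 0.1):
    """Ground truth for one direction: terrain blockage and canopy path.

    Marches the ray from the viewer (on the analytic ground surface) at
    ``step``-metre intervals out to ``max_range``.  Returns a dict with
    ``terrain_blocked`` (ray dips below the analytic terrain) and
    ``canopy_path_length`` (metres of ray inside the analytic canopy
    volume, exact to one step).
    """
    if isinstance(scene, SceneSpec):
        scene = Scene(scene)
    if zenith_deg >= 90.0 + 1e-9:
        raise ValueError("oracle directions must point at or above the horizontal")
    x0, y0 = point
    z0 = float(scene.terrain_elevation(np.float64(x0), np.float64(y0)))
    zen = np.radians(zenith_deg)
    az = np.radians(azimuth_deg)
    s = np.arange(step / 2.0, max_range, step)
    x = x0 + np.sin(zen) * np.sin(az) * s
    y = y0 + np.sin(zen) * np.cos(az) * s
    h = z0 + np.cos(zen) * s
    zt = scene.terrain_elevation(x, y)
    ch = scene.canopy_height(x, y)
    blocked = bool(np.any(h < zt - 1e-9))
    inside = (ch > 0) & (h >= zt) & (h <= zt + ch)
    return {
        "terrain_blocked": blocked,
        "canopy_path_length": float(inside.sum() * step),
        "free": not blocked and not inside.any(),
    }


def oracle_horizon(scene: Scene | SceneSpec, point: tuple[float, float],
                   azimuth_deg: float, max_range: float = 300.0,
                   step: float = 0.1) -> float:
    """Brute-force terrain horizon angle (degrees) along one azimuth."""
    if isinstance(scene, SceneSpec):
        scene = Scene(scene)
    x0, y0 = point
    z0 = float(scene.terrain_elevation(np.float64(x0), np.float64(y0)))
    az = np.radians(azimuth_deg)
    s = np.arange(step, max_range + step / 2.0, step)
    x = x0 + np.sin(az) * s
    y = y0 + np.cos(az) * s
    zt = scene.terrain_elevation(x, y)
    return float(np.degrees(np.arctan2(zt - z0, s)).max())
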