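"""Sub-canopy hemispheric images from a canopy height model.

For every direction on the 1°×1° (zenith, azimuth) hemisphere a ray is
marched from the viewer through the canopy volume — taken to fill the
column between the ground surface and ground + canopy height — and the
within-canopy path length l is accumulated, together with the
path-weighted foliage density Σ λ·l.  The Beer–Lambert transmission law

    p = exp(−G · Σ λ·l)

with projection function G (0.5 for randomly oriented foliage) converts
path length into a probability of a light ray penetrating the canopy,
which is then binarised into the canopy component of the hemispheric
image and intersected with the terrain-only image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ModelConfig
from .grids import CanopyHeightGrid, ElevationGrid, LambdaGrid
from .terrain_horizon import HemisphericImage, HorizonProfile

__all__ = [
    "PathLengthField",
    "TransmissionField",
    "canopy_horizon_and_thickness",
    "transmission_probability",
    "binarise_probability",
    "compose_images",
]


@dataclass
class PathLengthField:
    """Within-canopy path lengths per (zenith, azimuth) direction.

    ``l`` is the total ray length (m) spent inside canopy volume;
    ``lambda_l`` maps each leaf condition to the path-weighted foliage
    density Σ λ·l (dimensionless optical depth before the G factor).
    """

    l: np.ndarray
    lambda_l: dict[str, np.ndarray]
    canopy_top_horizon: HorizonProfile
    zenith_step: float = 1.0
    azimuth_step: float = 1.0

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if np.any(self.l < 0):
            raise ValueError("path lengths must be >= 0")
        for key, arr in self.lambda_l.items():
            self.lambda_l[key] = np.asarray(arr, dtype=float)
            if self.lambda_l[key].shape != self.l.shape:
                raise ValueError(f"lambda_l[{key!r}] shape mismatch")


@dataclass
class TransmissionField:
    """Per-direction probability of light penetrating the canopy."""

    p: np.ndarray
    zenith_step: float = 1.0
    azimuth_step: float = 1.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("transmission probabilities must lie in [0, 1]")


def canopy_horizon_and_thickness(
    chm: CanopyHeightGrid,
    dtm: ElevationGrid,
    point: tuple[float, float],
    lambda_grids: LambdaGrid | dict[str, LambdaGrid],
    config: ModelConfig | None = None,
) -> PathLengthField:
    """March rays through the canopy volume around ``point``.

    Rays start at the ground surface (plus any configured viewer height)
    and are sampled at ``config.canopy_ray_step`` metre intervals along the
    ray; a sample counts as inside canopy when its height lies between the
    ground elevation and ground + canopy height at its footprint.  Canopy
    height is sampled nearest-neighbour (crowns keep their crisp 1 m
    footprint), ground bilinearly.  Marching is capped at the local search
    radius and stops early once the ray clears the highest possible canopy
    top.  Several λ grids (e.g. leaf-on and leaf-off) can be accumulated in
    a single march.
    """
    config = config or ModelConfig()
    if isinstance(lambda_grids, LambdaGrid):
        lambda_grids = {lambda_grids.leaf_condition: lambda_grids}
    x0, y0 = float(point[0]), float(point[1])
    for grid, name in ((chm, "canopy height"), (dtm, "terrain")):
        if not grid.contains(x0, y0):
            raise ValueError(f"point {point} lies outside the {name} grid")
    r0, c0 = dtm.world_to_index(x0, y0)
    z_ground = ndimage.map_coordinates(dtm.values, [[r0], [c0]], order=1,
                                       mode="constant", cval=np.nan)[0]
    if np.isnan(z_ground):
        raise ValueError(f"terrain grid has nodata at point {point}")
    z_view = z_ground + config.viewer_height

    nz, na = config.n_zenith, config.n_azimuth
    step = config.canopy_ray_step
    zen = np.radians((np.arange(nz) + 0.5) * config.zenith_step)
    az = np.radians((np.arange(na) + 0.5) * config.azimuth_step)
    sin_az, cos_az = np.sin(az), np.cos(az)

    # horizontal range caps: local search radius and the grid's own reach
    xmin, ymin, xmax, ymax = chm.bounds
    reach = max(np.hypot(np.array([xmin, xmax]) - x0, ymin - y0).max(),
                np.hypot(np.array([xmin, xmax]) - x0, ymax - y0).max())
    horiz_cap = min(config.local_radius, reach)
    with np.errstate(invalid="ignore"):
        z_top_max = np.nanmax(dtm.values) + max(np.nanmax(chm.values), 0.0)

    l_total = np.zeros((nz, na))
    lam_total = {key: np.zeros((nz, na)) for key in lambda_grids}

    for iz in range(nz):
        cos_z, sin_z = np.cos(zen[iz]), np.sin(zen[iz])
        # stop once the ray clears the highest possible canopy top, or its
        # horizontal footprint leaves both the search radius and the grid
        caps = []
        if cos_z > 1e-9:
            caps.append((z_top_max - z_view) / cos_z + step
                        if z_top_max > z_view else step)
        if sin_z > 1e-9:
            caps.append(horiz_cap / sin_z + step)
        s_max = min(caps)
        n_steps = max(int(np.ceil(s_max / step)), 1)
        s = (np.arange(n_steps) + 0.5) * step                     # (ns,)
        x = x0 + sin_z * sin_az[:, None] * s[None, :]             # (na, ns)
        y = y0 + sin_z * cos_az[:, None] * s[None, :]
        h = z_view + cos_z * s                                    # (ns,)

        rows, cols = chm.world_to_index(x, y)
        ch = ndimage.map_coordinates(chm.values, [rows.ravel(), cols.ravel()],
                                     order=0, mode="constant", cval=0.0
                                     ).reshape(na, n_steps)
        ch = np.nan_to_num(ch, nan=0.0)
        rows_t, cols_t = dtm.world_to_index(x, y)
        zg = ndimage.map_coordinates(dtm.values, [rows_t.ravel(), cols_t.ravel()],
                                     order=1, mode="nearest"
                                     ).reshape(na, n_steps)
        inside = (ch > 0) & (h[None, :] >= zg) & (h[None, :] <= zg + ch)
        l_total[iz] = inside.sum(axis=1) * step
        for key, lgrid in lambda_grids.items():
            lr, lc = lgrid.world_to_index(x, y)
            lam = ndimage.map_coordinates(lgrid.values, [lr.ravel(), lc.ravel()],
                                          order=0, mode="constant", cval=0.0
                                          ).reshape(na, n_steps)
            lam = np.nan_to_num(lam, nan=0.0)
            lam_total[key][iz] = np.where(inside, lam, 0.0).sum(axis=1) * step

    # top-of-canopy horizon: highest elevation angle whose direction still
    # intersects canopy, per azimuth
    elev_centres = 90.0 - (np.arange(nz) + 0.5) * config.zenith_step
    blocked = l_total > 0
    top = np.full(na, -90.0)
    any_block = blocked.any(axis=0)
    if any_block.any():
        first = np.argmax(blocked, axis=0)  # lowest zenith index with canopy
        top[any_block] = elev_centres[first[any_block]]
    return PathLengthField(
        l=l_total,
        lambda_l=lam_total,
        canopy_top_horizon=HorizonProfile(top, config.azimuth_step),
        zenith_step=config.zenith_step,
        azimuth_step=config.azimuth_step,
    )


def transmission_probability(path_field: PathLengthField,
                             config: ModelConfig | None = None,
                             condition: str | None = None) -> TransmissionField:
    """Beer–Lambert transmission p = exp(−G · Σ λ·l) per direction."""
    config = config or ModelConfig()
    if condition is None:
        if len(path_field.lambda_l) != 1:
            raise ValueError("condition must be named when several λ accumulations exist")
        condition = next(iter(path_field.lambda_l))
    lam_l = path_field.lambda_l[condition]
    p = np.exp(-config.G * lam_l)
    return TransmissionField(p, path_field.zenith_step, path_field.azimuth_step)


def binarise_probability(field: TransmissionField, rng_seed: int | None = None,
                         mode: str = "stochastic") -> HemisphericImage:
    """Binarise per-direction transmission into a canopy sky image.

    ``stochastic`` draws one uniform variate per direction from a seeded
    generator and marks the direction sky where u < p, so the expected sky
    fraction equals p and a fixed seed reproduces the image bit for bit.
    Two transmission fields binarised with the same seed share their draws,
    which makes leaf-on/leaf-off images nested whenever λ_on ≥ λ_off.
    ``threshold`` marks sky deterministically where p ≥ 0.5.
    """
    if mode == "threshold":
        sky = field.p >= 0.5
    elif mode == "stochastic":
        rng = np.random.default_rng(0 if rng_seed is None else rng_seed)
        u = rng.random(field.p.shape)
        sky = u < field.p
    else:
        raise ValueError(f"unknown binarisation mode {mode!r}")
    return HemisphericImage(sky, field.zenith_step, field.azimuth_step)


def compose_images(terrain: HemisphericImage, canopy: HemisphericImage) -> HemisphericImage:
    """Intersect terrain and canopy images: sky needs both unobstructed."""
    if terrain.sky.shape != canopy.sky.shape:
        raise ValueError("hemispheric images differ in grid shape")
    return HemisphericImage(terrain.sky & canopy.sky,
                            terrain.zenith_step, terrain.azimuth_step)
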