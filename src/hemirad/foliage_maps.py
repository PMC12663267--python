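"""Per-pixel effective foliage density (λ) maps from forest-type mix rates.

Each 1 m canopy pixel gets a λ (m⁻¹) by linear interpolation between the
evergreen and deciduous endpoint values according to the pixel's evergreen
fraction: λ = f·λ_evergreen + (1−f)·λ_deciduous.  The deciduous endpoint
depends on the leaf condition (leaf-on/leaf-off) and on whether the pixel
is flagged as larch: alpine larch stands misclassified as broadleaf by the
dominant-leaf-type product (while the mix rate calls them mostly
deciduous) are forced to larch λ values above 1500 m elevation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import ModelConfig
from .grids import ElevationGrid, LambdaGrid, MixRateGrid

__all__ = ["interpolate_lambda", "larch_override", "resample_nearest"]

LARCH_ELEVATION_THRESHOLD = 1500.0  # m a.s.l.
LARCH_MIX_THRESHOLD = 0.5           # evergreen fraction below which larch is suspected


def resample_nearest(grid, target_resolution: float) -> np.ndarray:
    """Replicate a coarse grid onto a finer resolution by nearest neighbour.

    Only integer refinement factors are supported (e.g. 10 m → 1 m).
    """
    factor = grid.resolution / target_resolution
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"resolution {grid.resolution} m is not an integer multiple of {target_resolution} m"
        )
    factor = round(factor)
    return np.repeat(np.repeat(grid.values, factor, axis=0), factor, axis=1)


def larch_override(mix: MixRateGrid, ecoregion_is_needleleaf: np.ndarray,
                   dlt_is_broadleaf: np.ndarray,
                   elevation: ElevationGrid) -> np.ndarray:
    """Flag cells to be treated as larch forest.

    A cell is forced larch when, simultaneously, the ecoregion expects
    needleleaf forest, the dominant-leaf-type product says broadleaf, the
    mix rate calls the cell mostly deciduous (evergreen fraction < 0.5),
    and the cell lies above 1500 m a.s.l.  All inputs must share the mix
    grid's shape (the elevation grid is sampled at the mix cells' centres).
    """
    eco = np.asarray(ecoregion_is_needleleaf, dtype=bool)
    dlt = np.asarray(dlt_is_broadleaf, dtype=bool)
    if eco.shape != mix.shape or dlt.shape != mix.shape:
        raise ValueError("classification rasters are not co-registered with the mix grid")
    rows, cols = np.mgrid[0:mix.shape[0], 0:mix.shape[1]]
    x, y = mix.index_to_world(rows, cols)
    er, ec = elevation.world_to_index(x, y)
    elev = ndimage.map_coordinates(elevation.values, [er.ravel(), ec.ravel()],
                                   order=1, mode="nearest").reshape(mix.shape)
    with np.errstate(invalid="ignore"):
        flags = (eco & dlt
                 & (elev > LARCH_ELEVATION_THRESHOLD)
                 & (mix.values < LARCH_MIX_THRESHOLD))
    return flags


def interpolate_lambda(mix: MixRateGrid, condition: str,
                       config: ModelConfig | None = None,
                       forced_larch: np.ndarray | None = None,
                       target_resolution: float = 1.0) -> LambdaGrid:
    """Build a λ grid for one leaf condition.

    The mix-rate raster (nominally 10 m) is replicated to the canopy
    resolution (nominally 1 m) by nearest neighbour, then λ is linearly
    interpolated per cell between λ_evergreen (f = 1) and the deciduous
    endpoint for the condition (f = 0); forced-larch cells swap in the
    larch deciduous endpoint.  Nodata mix cells yield λ = 0 (no foliage).
    """
    config = config or ModelConfig()
    if condition not in ("leaf_on", "leaf_off"):
        raise ValueError(f"unknown leaf condition {condition!r}")
    if forced_larch is None:
        forced_larch = np.zeros(mix.shape, dtype=bool)
    forced_larch = np.asarray(forced_larch, dtype=bool)
    if forced_larch.shape != mix.shape:
        raise ValueError("forced-larch flags are not co-registered with the mix grid")

    f = mix.values
    lam_ever = config.lambda_evergreen
    lam_dec = np.where(forced_larch,
                       config.lambda_value(condition, "forced_larch"),
                       config.lambda_value(condition, "broadleaf_region"))
    lam = f * lam_ever + (1.0 - f) * lam_dec
    lam = np.nan_to_num(lam, nan=0.0)

    if mix.resolution != target_resolution:
        factor = mix.resolution / target_resolution
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("target resolution must integer-divide the mix resolution")
        factor = round(factor)
        lam = np.repeat(np.repeat(lam, factor, axis=0), factor, axis=1)
    return LambdaGrid(values=lam, resolution=target_resolution, origin=mix.origin,
                      crs_epsg=mix.crs_epsg, leaf_condition=condition)
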