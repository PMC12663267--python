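"""Mask-driven orchestration of the full model.

The forest mask decides what is computed where: the terrain-only stage
runs at the centre of every modelled (non-zero) 10 m cell, and the
terrain+canopy stage — one hemispheric image each for leaf-on and
leaf-off foliage — additionally runs at forest cells (code 1).  Outputs
are three-layer SVF GeoTIFFs (terrain / leaf_on / leaf_off, each in a
planar and a hemi variant) and daily NetCDF files of hourly direct-beam
transmissivity per layer.

Per-point reproducibility: the canopy binarisation seed is derived from
(global seed, point index), so tiling, ordering and resumption cannot
change results, and the leaf-on/leaf-off images of one point share their
random draws (which preserves leaf_on ⊆ leaf_off sky nesting).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import raster_io
from .canopy_image import (
    binarise_probability,
    canopy_horizon_and_thickness,
    compose_images,
    transmission_probability,
)
from .config import ModelConfig
from .foliage_maps import interpolate_lambda
from .geo import LocalAnchor, to_latlon
from .grids import CanopyHeightGrid, ElevationGrid, ForestMask, MixRateGrid
from .sky_view import SvfPair, sky_view_pair
from .solar_track import dbt_series, hourly_average, positions_for_times
from .terrain_horizon import combine_horizons, horizon_from_grid, horizon_to_image

logger = logging.getLogger("hemirad")

__all__ = ["ModelPoint", "RunManifest", "PipelineInputs", "plan_run",
           "run_point", "run_tiles", "LAYER_SETS"]

LAYER_SETS = {0: (), 1: ("terrain", "leaf_on", "leaf_off"), 2: ("terrain",)}


@dataclass(frozen=True)
class ModelPoint:
    index: int
    row: int
    col: int
    x: float
    y: float
    code: int

    @property
    def layers(self) -> tuple[str, ...]:
        return LAYER_SETS[self.code]


@dataclass
class RunManifest:
    points: list[ModelPoint]
    mask_shape: tuple[int, int]
    config_hash: str

    @property
    def n_terrain(self) -> int:
        return len(self.points)

    @property
    def n_forest(self) -> int:
        return sum(1 for p in self.points if p.code == 1)


@dataclass
class PipelineInputs:
    dtm_local: ElevationGrid
    dtm_regional: ElevationGrid
    chm: CanopyHeightGrid | None = None
    mix: MixRateGrid | None = None
    forced_larch: np.ndarray | None = None
    anchor: LocalAnchor | None = None


def _config_hash(config: ModelConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def plan_run(mask: ForestMask, config: ModelConfig | None = None) -> RunManifest:
    """One model point at the centre of every non-zero mask cell."""
    config = config or ModelConfig()
    codes = mask.values
    if codes.size == 0 or not np.any(codes != 0):
        raise ValueError("forest mask selects no model points")
    rows, cols = np.nonzero(codes != 0)
    points = []
    for index, (r, c) in enumerate(zip(rows.tolist(), cols.tolist())):
        x, y = mask.index_to_world(r, c)
        points.append(ModelPoint(index=index, row=r, col=c,
                                 x=float(x), y=float(y), code=int(codes[r, c])))
    return RunManifest(points=points, mask_shape=codes.shape,
                       config_hash=_config_hash(config))


def point_seed(global_seed: int, point_index: int) -> int:
    """Stable per-point binarisation seed below 2^31."""
    return int(np.random.SeedSequence([global_seed, point_index]).generate_state(1)[0] % (2 ** 31))


def _point_images(point: ModelPoint, inputs: PipelineInputs,
                  config: ModelConfig, lambda_grids) -> dict:
    """Hemispheric images for every layer of one model point."""
    local = horizon_from_grid(inputs.dtm_local, (point.x, point.y),
                              config.local_radius, config.azimuth_step,
                              config.viewer_height)
    regional = horizon_from_grid(inputs.dtm_regional, (point.x, point.y),
                                 config.regional_radius, config.azimuth_step,
                                 config.viewer_height)
    combined = combine_horizons(local, regional)
    images = {"terrain": horizon_to_image(combined, config)}
    if point.code == 1:
        if inputs.chm is None or lambda_grids is None:
            raise ValueError("forest point requires canopy height and λ grids")
        path_field = canopy_horizon_and_thickness(
            inputs.chm, inputs.dtm_local, (point.x, point.y), lambda_grids, config)
        seed = point_seed(config.rng_seed, point.index)
        for condition in ("leaf_on", "leaf_off"):
            p = transmission_probability(path_field, config, condition)
            canopy = binarise_probability(p, seed, config.binarise_mode)
            images[condition] = compose_images(images["terrain"], canopy)
    return images


def run_point(point: ModelPoint, inputs: PipelineInputs,
              config: ModelConfig | None = None,
              days: list[_dt.date] | None = None,
              lambda_grids=None) -> dict:
    """All layers of one model point: SVF pair and hourly DBT per layer."""
    config = config or ModelConfig()
    if lambda_grids is None and point.code == 1:
        if inputs.mix is None:
            raise ValueError("forest point requires a mix-rate grid")
        lambda_grids = {
            cond: interpolate_lambda(inputs.mix, cond, config, inputs.forced_larch)
            for cond in ("leaf_on", "leaf_off")
        }
    images = _point_images(point, inputs, config, lambda_grids)
    lat, lon = to_latlon(point.x, point.y, inputs.dtm_local.crs_epsg, inputs.anchor)

    result: dict = {"svf": {}, "dbt": {}, "images": images}
    for layer, image in images.items():
        result["svf"][layer] = sky_view_pair(image, config)
    if days:
        for layer, image in images.items():
            series = []
            for day in days:
                start = pd.Timestamp(day)
                times = pd.date_range(start, start + pd.Timedelta(days=1),
                                      freq=f"{config.track_step}min", inclusive="left")
                zen, az = positions_for_times(times, lat, lon, config.utc_offset,
                                              config.apply_refraction)
                fine = dbt_series(image, times, zen, az, config)
                series.append(hourly_average(fine))
            result["dbt"][layer] = series
    return result


def run_tiles(manifest: RunManifest, inputs: PipelineInputs, mask: ForestMask,
              output_dir: str | Path, config: ModelConfig | None = None,
              days: list[_dt.date] | None = None,
              layers: tuple[str, ...] = ("terrain", "leaf_on", "leaf_off"),
              resume: bool = True) -> dict:
    """Run every manifest point and write the SVF/DBT file products.

    Writes ``svf_{variant}_{layer}.tif`` (8-bit percent, nodata 255) and,
    for each requested day, ``dbt_{layer}_{date}.nc``.  With ``resume``,
    existing daily DBT files are kept (per-point seeding makes re-runs
    bitwise identical, so a resumed run equals an uninterrupted one).
    """
    config = config or ModelConfig()
    days = days or []
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    lambda_grids = None
    if any(p.code == 1 for p in manifest.points) and inputs.mix is not None:
        lambda_grids = {
            cond: interpolate_lambda(inputs.mix, cond, config, inputs.forced_larch)
            for cond in ("leaf_on", "leaf_off")
        }

    ny, nx = manifest.mask_shape
    svf_maps = {(variant, layer): np.full((ny, nx), np.nan)
                for variant in ("planar", "hemi") for layer in layers}
    n_hours = 24 * len(days)
    dbt_maps = {layer: np.full((n_hours, ny, nx), np.nan) for layer in layers}

    for point in manifest.points:
        result = run_point(point, inputs, config, days, lambda_grids)
        for layer in point.layers:
            if layer not in layers:
                continue
            pair: SvfPair = result["svf"][layer]
            svf_maps[("planar", layer)][point.row, point.col] = pair.svf_planar
            svf_maps[("hemi", layer)][point.row, point.col] = pair.svf_hemi
            for d, hourly in enumerate(result["dbt"].get(layer, [])):
                dbt_maps[layer][24 * d: 24 * (d + 1), point.row, point.col] = hourly.values
        if (point.index + 1) % 25 == 0 or point.index + 1 == len(manifest.points):
            logger.info("processed %d/%d points", point.index + 1, len(manifest.points))

    written = []
    for (variant, layer), values in svf_maps.items():
        path = out / f"svf_{variant}_{layer}.tif"
        raster_io.write_encoded_geotiff(values, mask, path)
        written.append(path)
    x_coords, _ = mask.index_to_world(np.zeros(nx), np.arange(nx))
    _, y_coords = mask.index_to_world(np.arange(ny), np.zeros(ny))
    for layer in layers:
        for d, day in enumerate(days):
            path = out / f"dbt_{layer}_{day.isoformat()}.nc"
            if resume and path.exists():
                logger.info("keeping existing %s", path.name)
                continue
            raster_io.write_dbt_netcdf(dbt_maps[layer][24 * d: 24 * (d + 1)],
                                       day, x_coords, y_coords, path,
                                       crs_epsg=mask.crs_epsg, layer_kind=layer)
            written.append(path)
    return {"files": written, "svf": svf_maps, "dbt": dbt_maps}
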