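"""GeoTIFF and NetCDF input/output with the dataset's encoding conventions.

Grids travel as single-band GeoTIFFs in a projected metric CRS; hourly
direct-beam transmissivity travels as daily NetCDF files with (time, y, x)
dimensions.  Fractional layers (SVF, DBT) are stored as 8-bit integer
percentages 0–100.  GeoTIFFs use 255 as the nodata sentinel; the NetCDF
files use -1 because the classic NetCDF byte type is signed.

GeoTIFF georeferencing is written/read through the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) on top of
tifffile.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .grids import (
    RasterGrid,
    ElevationGrid,
    CanopyHeightGrid,
    ForestMask,
    MixRateGrid,
)

__all__ = [
    "read_grid",
    "write_grid",
    "encode_fraction",
    "decode_fraction",
    "write_encoded_geotiff",
    "write_dbt_netcdf",
    "read_dbt_netcdf",
    "ENCODED_NODATA_TIFF",
    "ENCODED_NODATA_NETCDF",
]

ENCODED_NODATA_TIFF = 255
ENCODED_NODATA_NETCDF = -1

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_KIND_CLASSES = {
    "elevation": ElevationGrid,
    "canopy_height": CanopyHeightGrid,
    "forest_mask": ForestMask,
    "mix_rate": MixRateGrid,
    "encoded": RasterGrid,
}

# EPSG codes of geographic (degree-unit) CRSs we refuse outright
_GEOGRAPHIC_EPSG = {4326, 4258, 4617, 4269}


# ---------------------------------------------------------------------------
# percent encoding


def encode_fraction(values) -> np.ndarray:
    """Encode fractions in [0, 1] as integer percentages 0–100 (uint8).

    Rounds half-up (0.665 → 67 at percent scale).  NaN encodes to the
    255 nodata sentinel.  Out-of-range values raise: they signal an
    upstream bug, not data to be clamped.
    """
    arr = np.asarray(values, dtype=float)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > 1)):
        bad = arr[valid][(arr[valid] < 0) | (arr[valid] > 1)]
        raise ValueError(f"fractions outside [0, 1] cannot be encoded: {bad[:5]!r}")
    out = np.full(arr.shape, ENCODED_NODATA_TIFF, dtype=np.uint8)
    out[valid] = np.floor(arr[valid] * 100.0 + 0.5).astype(np.uint8)
    return out


def decode_fraction(encoded, nodata: int = ENCODED_NODATA_TIFF) -> np.ndarray:
    """Decode integer percentages back to fractions; nodata → NaN."""
    arr = np.asarray(encoded)
    out = arr.astype(float) / 100.0
    out[arr == nodata] = np.nan
    valid = ~np.isnan(out)
    if np.any((out[valid] < 0) | (out[valid] > 1)):
        raise ValueError("encoded layer contains values outside 0–100")
    return out


# ---------------------------------------------------------------------------
# GeoTIFF


def _geokeys(epsg: int) -> tuple[int, ...]:
    # GeoKeyDirectory: header (version, revision, minor, nkeys) then
    # (key, location, count, value) quadruples.  Model type 1 = projected,
    # raster type 1 = PixelIsArea, 3072 = projected CRS EPSG code.
    keys = [(1024, 0, 1, 1), (1025, 0, 1, 1), (3072, 0, 1, epsg)]
    flat = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def write_grid(grid: RasterGrid, path: str | Path, dtype=None) -> Path:
    """Write a grid as a single-band GeoTIFF with projected georeferencing."""
    path = Path(path)
    values = grid.values
    if dtype is not None:
        values = values.astype(dtype)
    nodata = grid.nodata
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)
        nodata_str = "nan" if nodata is None else repr(float(nodata))
    else:
        nodata_str = "" if nodata is None else repr(int(nodata))
    geokeys = _geokeys(int(grid.crs_epsg))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.resolution), float(grid.resolution), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
    ]
    if nodata_str:
        extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_str) + 1, nodata_str))
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def read_grid(path: str | Path, expected_kind: str) -> RasterGrid:
    """Read a single-band GeoTIFF as a typed grid.

    ``expected_kind`` is one of ``elevation``, ``canopy_height``,
    ``forest_mask``, ``mix_rate`` or ``encoded``; the grid-type invariants
    are enforced on read.  Geographic (degree-unit) rasters are rejected.
    """
    path = Path(path)
    if expected_kind not in _KIND_CLASSES:
        raise ValueError(f"unknown grid kind {expected_kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path} lacks GeoTIFF georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        epsg = 0
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            nkeys = keys[3]
            for i in range(nkeys):
                key, _, _, value = keys[4 + 4 * i : 8 + 4 * i]
                if key == 1024 and value == 2:
                    raise ValueError(f"{path} is in a geographic CRS; a projected metric CRS is required")
                if key in (3072, 2048):
                    epsg = int(value)
        if epsg in _GEOGRAPHIC_EPSG:
            raise ValueError(f"{path} is in geographic EPSG:{epsg}; a projected metric CRS is required")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value.strip().strip("\x00")
            if raw:
                nodata = float(raw) if ("." in raw or raw == "nan") else int(raw)
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError(f"{path} has anisotropic pixels; square cells are required")
    resolution = float(scale[0])
    origin = (float(tie[3]), float(tie[4]))

    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(float)
        if nodata is not None and not np.isnan(nodata):
            values[values == nodata] = np.nan
            nodata = None
    elif expected_kind == "forest_mask" and nodata is not None:
        values = np.where(values == nodata, 0, values)
        nodata = None

    cls = _KIND_CLASSES[expected_kind]
    kwargs = dict(values=values, resolution=resolution, origin=origin,
                  crs_epsg=epsg, nodata=nodata)
    return cls(**kwargs)


def write_encoded_geotiff(fractions: np.ndarray, like: RasterGrid,
                          path: str | Path) -> Path:
    """Encode a fraction layer to 0–100 uint8 and write it with ``like``'s
    georeferencing (nodata 255)."""
    encoded = encode_fraction(fractions)
    grid = RasterGrid(values=encoded, resolution=like.resolution,
                      origin=like.origin, crs_epsg=like.crs_epsg,
                      nodata=ENCODED_NODATA_TIFF)
    return write_grid(grid, path)


# ---------------------------------------------------------------------------
# NetCDF (daily DBT files)


def write_dbt_netcdf(dbt: np.ndarray, day: _dt.date, x: np.ndarray,
                     y: np.ndarray, path: str | Path,
                     crs_epsg: int = 2056, layer_kind: str = "terrain") -> Path:
    """Write one day of hourly DBT fractions to a NetCDF file.

    ``dbt`` has shape (24, ny, nx) with values in [0, 1] or NaN.  Values are
    stored as signed 8-bit percentages (fill -1).  The time coordinate
    counts hours since local midnight of ``day`` in fixed-offset UTC+1
    (CET); each timestamp marks the beginning of its averaging period.
    """
    dbt = np.asarray(dbt, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if dbt.ndim != 3 or dbt.shape[0] != 24:
        raise ValueError(f"expected 24 hourly steps of shape (24, ny, nx); got {dbt.shape}")
    if dbt.shape[1:] != (y.size, x.size):
        raise ValueError("dbt spatial shape does not match the x/y coordinates")
    encoded = encode_fraction(dbt).astype(np.int8)
    encoded[np.isnan(dbt)] = ENCODED_NODATA_NETCDF

    ds = xr.Dataset(
        {
            "dbt": (
                ("time", "y", "x"),
                encoded,
                {
                    "long_name": "direct-beam transmissivity",
                    "units": "percent",
                    "_FillValue": np.int8(ENCODED_NODATA_NETCDF),
                    "comment": "8-bit percentage 0-100; divide by 100 for fractions",
                    "layer_kind": layer_kind,
                },
            )
        },
        coords={
            "time": (
                "time",
                np.arange(24, dtype=np.int32),
                {
                    "units": f"hours since {day.isoformat()} 00:00:00 +01:00",
                    "long_name": "start of hourly averaging period",
                    "timezone": "CET (fixed UTC+1)",
                },
            ),
            "x": ("x", x, {"units": "m", "standard_name": "projection_x_coordinate"}),
            "y": ("y", y, {"units": "m", "standard_name": "projection_y_coordinate"}),
        },
        attrs={"crs_epsg": np.int32(crs_epsg), "Conventions": "CF-1.8"},
    )
    path = Path(path)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_dbt_netcdf(path: str | Path):
    """Read a daily DBT file; returns (dbt fractions, times, x, y).

    ``times`` is a pandas DatetimeIndex of naive timestamps representing
    fixed-offset UTC+1 civil time.
    """
    with xr.open_dataset(path, engine="scipy", decode_cf=False) as ds:
        encoded = ds["dbt"].values
        units = str(ds["time"].attrs["units"])
        hours = np.asarray(ds["time"].values)
        x = np.asarray(ds["x"].values)
        y = np.asarray(ds["y"].values)
    # "hours since YYYY-MM-DD 00:00:00 +01:00"
    base = pd.Timestamp(units.split("since", 1)[1].strip().split(" +")[0])
    times = base + pd.to_timedelta(hours, unit="h")
    dbt = decode_fraction(encoded, nodata=ENCODED_NODATA_NETCDF)
    return dbt, pd.DatetimeIndex(times), x, y
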