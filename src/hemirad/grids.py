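"""Georeferenced raster containers used throughout the model.

All grids are axis-aligned, single-band arrays in a projected metric CRS.
Row 0 is the northern edge; ``origin`` is the (x, y) of the top-left *corner*
of the top-left cell, so the centre of cell (row, col) sits at::

    x = origin_x + (col + 0.5) * resolution
    y = origin_y - (row + 0.5) * resolution

Nodata is represented as NaN in float grids and as an explicit sentinel in
integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RasterGrid",
    "ElevationGrid",
    "CanopyHeightGrid",
    "ForestMask",
    "MixRateGrid",
    "LambdaGrid",
]


@dataclass
class RasterGrid:
    """A single-band georeferenced raster in a projected metric CRS."""

    values: np.ndarray
    resolution: float
    origin: tuple[float, float]
    crs_epsg: int = 2056
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        self._validate()

    def _validate(self) -> None:
        if np.issubdtype(self.values.dtype, np.floating):
            finite = np.isfinite(self.values) | np.isnan(self.values)
            if not finite.all():
                raise ValueError("non-nodata raster values must be finite")

    # -- georeferencing helpers -------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0 - rows * self.resolution, x0 + cols * self.resolution, y0)

    def world_to_index(self, x, y):
        """Fractional (row, col) array indices of world coordinates.

        Index (0, 0) is the centre of the top-left cell, so a point at a cell
        centre maps onto integer indices.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.origin[0]) / self.resolution - 0.5
        row = (self.origin[1] - y) / self.resolution - 0.5
        return row, col

    def index_to_world(self, row, col):
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin[0] + (col + 0.5) * self.resolution
        y = self.origin[1] - (row + 0.5) * self.resolution
        return x, y

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=values)


@dataclass
class ElevationGrid(RasterGrid):
    """Bare-earth terrain heights (m a.s.l.); NaN marks nodata."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()


@dataclass
class CanopyHeightGrid(RasterGrid):
    """Canopy height above ground (m); 0 or NaN where there is no canopy."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("canopy heights must be >= 0")


@dataclass
class ForestMask(RasterGrid):
    """Per-cell run codes: 0 = no model run, 1 = forest, 2 = open."""

    VALID_CODES = (0, 1, 2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.asarray(self.values, dtype=float)
            if not np.allclose(rounded, np.round(rounded), equal_nan=False):
                raise ValueError("forest mask must contain integer codes")
            self.values = rounded.astype(np.int16)
        super().__post_init__()
        bad = ~np.isin(self.values, self.VALID_CODES)
        if bad.any():
            raise ValueError(
                f"forest mask contains invalid codes {np.unique(self.values[bad])!r}; "
                "only 0 (no run), 1 (forest), 2 (open) are allowed"
            )


@dataclass
class MixRateGrid(RasterGrid):
    """Evergreen fraction per cell in [0, 1]; NaN marks nodata."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()
        with np.errstate(invalid="ignore"):
            if np.any((self.values < 0) | (self.values > 1)):
                raise ValueError("mix-rate (evergreen fraction) must lie in [0, 1]")


@dataclass
class LambdaGrid(RasterGrid):
    """Effective foliage area volume density λ (m⁻¹) per canopy cell.

    ``leaf_condition`` records which foliage state the grid encodes.
    """

    leaf_condition: str = field(default="leaf_on")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()
        if self.leaf_condition not in ("leaf_on", "leaf_off"):
            raise ValueError(f"unknown leaf condition {self.leaf_condition!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("foliage density must be >= 0")
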