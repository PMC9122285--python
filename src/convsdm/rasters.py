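"""Raster layers, resampling, patch extraction and point environment vectors.

All geometry is planar (a local projected CRS in meters is assumed). A raster
layer is a north-up grid of square pixels: row 0 is the northmost row, and the
pixel at (row, col) covers the half-open square

    x in [x0 + col * res, x0 + (col + 1) * res)
    y in (y0 - (row + 1) * res, y0 - row * res]

where ``(x0, y0)`` is the coordinate of the layer's top-left corner. The point
``(x, y)`` therefore belongs to exactly one pixel, found by flooring.

Continuous layers are resampled bilinearly (smooth interpolation); categorical
layers only by nearest neighbor, which is the sole method that preserves the
class set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterLayer",
    "EnvironmentalTensor",
    "BoundaryError",
    "NodataError",
    "CoverageError",
    "CategoricalResampleError",
    "resample_layer",
    "extract_patch",
    "env_vector_at",
    "write_raster",
    "read_raster",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class BoundaryError(ValueError):
    """A requested patch crosses the border of a layer (no implicit padding)."""


class NodataError(ValueError):
    """A nodata cell fell inside a patch that must be fully valid."""


class CoverageError(ValueError):
    """A query point lies outside the extent of every raster."""


class CategoricalResampleError(ValueError):
    """Bilinear interpolation was requested on a categorical layer."""


@dataclass
class RasterLayer:
    """A single-band north-up raster with square pixels.

    Parameters
    ----------
    name : str
        Layer label (e.g. ``"red"``, ``"land_cover"``, ``"elevation"``).
    grid : ndarray of shape (rows, cols)
        Cell values; row 0 is the northmost row.
    resolution : float
        Pixel edge length in meters.
    origin : tuple of float
        ``(x, y)`` of the top-left corner of the top-left pixel.
    kind : {"continuous", "categorical"}
    nodata : float or None
        Marker value for missing cells (compared with ``==``; NaN is also
        always treated as missing in continuous layers).
    """

    name: str
    grid: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    kind: str = CONTINUOUS
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"layer grid must be 2D, got shape {self.grid.shape}")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        rows, cols = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0 - rows * self.resolution, x0 + cols * self.resolution, y0)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        # half-open convention: the top/left edges belong to the raster,
        # the bottom/right edges do not (x half-open right, y half-open down)
        return xmin <= x < xmax and ymin < y <= ymax

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the pixel whose half-open extent contains the point."""
        if not self.contains(x, y):
            raise CoverageError(
                f"point ({x}, {y}) outside layer {self.name!r} extent {self.extent}"
            )
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.resolution))
        # a point on a horizontal pixel edge belongs to the pixel *below* the
        # edge in grid terms, i.e. the one whose top edge it is: plain floor
        row = int(np.floor((y0 - y) / self.resolution))
        row = min(max(row, 0), self.grid.shape[0] - 1)
        col = min(max(col, 0), self.grid.shape[1] - 1)
        return row, col

    def is_missing(self, values: np.ndarray) -> np.ndarray:
        miss = np.zeros(np.shape(values), dtype=bool)
        if self.nodata is not None:
            miss |= np.asarray(values) == self.nodata
        if self.kind == CONTINUOUS:
            miss |= np.isnan(np.asarray(values, dtype=float))
        return miss


@dataclass
class EnvironmentalTensor:
    """A C x H x W patch of co-registered raster channels centered on a point.

    ``channel_meta`` is a list of ``(name, kind)`` pairs aligned with the
    leading axis of ``channels``. The patch is square (H == W) and the pixel
    containing the center point sits at index ``(P // 2, P // 2)``.
    """

    channels: np.ndarray
    channel_meta: list[tuple[str, str]]
    center: tuple[float, float]
    resolution: float

    def __post_init__(self) -> None:
        c, h, w = self.channels.shape
        if h != w:
            raise ValueError(f"patch must be square, got {h}x{w}")
        if c != len(self.channel_meta):
            raise ValueError("channel_meta length must match channel count")

    @property
    def patch_px(self) -> int:
        return self.channels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        for i, (n, _) in enumerate(self.channel_meta):
            if n == name:
                return self.channels[i]
        raise KeyError(name)


def resample_layer(layer: RasterLayer, target_resolution: float, method: str | None = None) -> RasterLayer:
    """Resample a layer to a new resolution, preserving its extent.

    Continuous layers are interpolated bilinearly; categorical layers use the
    nearest source cell so the class set is kept intact. Requesting bilinear
    interpolation on a categorical layer raises :class:`CategoricalResampleError`.
    Resampling to the layer's own resolution returns an equal grid.
    """
    if target_resolution <= 0:
        raise ValueError(f"target resolution must be positive, got {target_resolution}")
    if method is None:
        method = "nearest" if layer.kind == CATEGORICAL else "bilinear"
    if layer.kind == CATEGORICAL and method == "bilinear":
        raise CategoricalResampleError(
            f"bilinear resampling would corrupt classes of categorical layer {layer.name!r}"
        )

    rows, cols = layer.grid.shape
    height = rows * layer.resolution
    width = cols * layer.resolution
    out_rows = max(1, int(round(height / target_resolution)))
    out_cols = max(1, int(round(width / target_resolution)))
    if out_rows == rows and out_cols == cols:
        return replace(layer, grid=layer.grid.copy(), resolution=target_resolution)

    # target pixel centers expressed in source pixel-index coordinates
    r_idx = ((np.arange(out_rows) + 0.5) * target_resolution) / layer.resolution - 0.5
    c_idx = ((np.arange(out_cols) + 0.5) * target_resolution) / layer.resolution - 0.5

    if method == "nearest":
        rr = np.clip(np.round(r_idx).astype(int), 0, rows - 1)
        cc = np.clip(np.round(c_idx).astype(int), 0, cols - 1)
        out = layer.grid[np.ix_(rr, cc)]
    elif method == "bilinear":
        rr, cc = np.meshgrid(np.clip(r_idx, 0, rows - 1), np.clip(c_idx, 0, cols - 1), indexing="ij")
        out = ndimage.map_coordinates(
            layer.grid.astype(float), [rr, cc], order=1, mode="nearest"
        )
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return replace(layer, grid=out, resolution=target_resolution)


def extract_patch(
    layers: list[RasterLayer],
    center: tuple[float, float],
    patch_px: int,
) -> EnvironmentalTensor:
    """Stack a square patch of every layer, centered on a point.

    All layers must share resolution and contain the full patch. For a patch of
    P pixels per side the pixel containing the center is placed at index
    ``(P // 2, P // 2)``; the patch spans source indices
    ``[idx - P // 2, idx - P // 2 + P)`` on each axis (row 0 northmost).

    Raises
    ------
    BoundaryError
        If the patch would cross a layer border (no implicit padding).
    NodataError
        If a missing cell falls inside the patch.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    if not layers:
        raise ValueError("no layers given")
    res = layers[0].resolution
    for lyr in layers:
        if lyr.resolution != res:
            raise ValueError(
                f"layers must share a common resolution; {lyr.name!r} has "
                f"{lyr.resolution}, expected {res}"
            )

    half = patch_px // 2
    channels = np.empty((len(layers), patch_px, patch_px), dtype=float)
    for i, lyr in enumerate(layers):
        row, col = lyr.index_of(*center)
        r0, c0 = row - half, col - half
        r1, c1 = r0 + patch_px, c0 + patch_px
        nrows, ncols = lyr.grid.shape
        if r0 < 0 or c0 < 0 or r1 > nrows or c1 > ncols:
            raise BoundaryError(
                f"patch of {patch_px}px at {center} crosses border of layer "
                f"{lyr.name!r} (rows {r0}:{r1}, cols {c0}:{c1} of {nrows}x{ncols})"
            )
        block = lyr.grid[r0:r1, c0:c1]
        if lyr.is_missing(block).any():
            raise NodataError(f"nodata inside patch at {center} in layer {lyr.name!r}")
        channels[i] = block
    meta = [(lyr.name, lyr.kind) for lyr in layers]
    return EnvironmentalTensor(channels, meta, center, res)


def env_vector_at(
    env_rasters: list[RasterLayer], point: tuple[float, float]
) -> tuple[np.ndarray, list[str]]:
    """Point-value environment vector: one value per raster at the containing cell.

    Missing cells yield NaN (an explicit missing marker, never 0). A point
    outside the extent of *every* raster raises :class:`CoverageError`; a point
    covered by some rasters but not others gets NaN for the uncovered ones.
    """
    values = np.full(len(env_rasters), np.nan)
    names = [lyr.name for lyr in env_rasters]
    any_inside = False
    for i, lyr in enumerate(env_rasters):
        if not lyr.contains(*point):
            continue
        any_inside = True
        row, col = lyr.index_of(*point)
        v = lyr.grid[row, col]
        values[i] = np.nan if lyr.is_missing(v) else float(v)
    if not any_inside:
        raise CoverageError(f"point {point} outside the coverage of all rasters")
    return values, names


def write_raster(path, layer: RasterLayer) -> None:
    """Write a layer as a single-band TIFF with georeferencing in the description tag."""
    import tifffile

    meta = {
        "name": layer.name,
        "resolution": layer.resolution,
        "origin": list(layer.origin),
        "kind": layer.kind,
        "nodata": layer.nodata,
    }
    tifffile.imwrite(str(path), layer.grid, description=json.dumps(meta))


def read_raster(path) -> RasterLayer:
    """Read a layer written by :func:`write_raster`."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        meta = json.loads(page.tags["ImageDescription"].value)
    return RasterLayer(
        name=meta["name"],
        grid=grid,
        resolution=float(meta["resolution"]),
        origin=tuple(meta["origin"]),
        kind=meta["kind"],
        nodata=meta["nodata"],
    )
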