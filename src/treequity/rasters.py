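"""Minimal planar raster container and zonal helpers.

All grids in this package live on a planar metric grid (no geodesy). The
convention is a lower-left origin: array row 0 is the southernmost row, pixel
(i, j) has its center at ``(x0 + (j + 0.5) * res, y0 + (i + 0.5) * res)``.
Rasters are persisted as plain TIFF with a JSON sidecar carrying the
georeferencing (resolution, origin, nodata, band names).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

import tifffile

__all__ = ["Raster", "pixel_centers", "zonal_mask", "zonal_mean", "zonal_fraction"]


@dataclass
class Raster:
    """A single- or multi-band raster on a planar grid.

    data has shape (H, W) or (bands, H, W); ``res_m`` is the pixel size in
    meters and ``origin`` the (x, y) of the grid's lower-left corner.
    """

    data: np.ndarray
    res_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    band_names: list[str] = field(default_factory=list)
    nodata: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    def band(self, name: str) -> np.ndarray:
        return self.data[self.band_names.index(name)]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.ascontiguousarray(self.data))
        meta = {
            "res_m": self.res_m,
            "origin": list(self.origin),
            "band_names": self.band_names,
            "nodata": self.nodata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=data,
            res_m=meta["res_m"],
            origin=tuple(meta["origin"]),
            band_names=meta["band_names"],
            nodata=meta["nodata"],
        )


def pixel_centers(
    shape: tuple[int, int], res_m: float, origin: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Center coordinates of every pixel: two (H, W) arrays (x, y)."""
    h, w = shape
    x = origin[0] + (np.arange(w) + 0.5) * res_m
    y = origin[1] + (np.arange(h) + 0.5) * res_m
    return np.meshgrid(x, y)


def zonal_mask(
    shape: tuple[int, int],
    res_m: float,
    polygon: BaseGeometry,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose *centers* fall inside ``polygon``.

    Pixel-center containment is the zonal convention used throughout the
    package, for both the 2 m canopy grid and the 30 m thermal grid.
    """
    h, w = shape
    minx, miny, maxx, maxy = polygon.bounds
    # candidate index window (half-open) around the polygon bounds
    j0 = max(0, int(np.floor((minx - origin[0]) / res_m - 0.5)))
    j1 = min(w, int(np.ceil((maxx - origin[0]) / res_m + 0.5)))
    i0 = max(0, int(np.floor((miny - origin[1]) / res_m - 0.5)))
    i1 = min(h, int(np.ceil((maxy - origin[1]) / res_m + 0.5)))
    mask = np.zeros((h, w), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return mask
    xs = origin[0] + (np.arange(j0, j1) + 0.5) * res_m
    ys = origin[1] + (np.arange(i0, i1) + 0.5) * res_m
    gx, gy = np.meshgrid(xs, ys)
    mask[i0:i1, j0:j1] = contains_xy(polygon, gx, gy)
    return mask


def zonal_mean(
    grid: np.ndarray,
    res_m: float,
    polygon: BaseGeometry,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Mean of in-zone pixel values, ignoring NaN. NaN if the zone is empty."""
    mask = zonal_mask(grid.shape, res_m, polygon, origin)
    vals = grid[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def zonal_fraction(
    mask_grid: np.ndarray,
    res_m: float,
    polygon: BaseGeometry,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Fraction of polygon area covered by 1-pixels (pixel-center rule).

    (count of 1-pixels with centers inside) * pixel_area / polygon area,
    clipped to [0, 1].
    """
    if polygon.area <= 0:
        raise ValueError("zero-area polygon")
    zmask = zonal_mask(mask_grid.shape, res_m, polygon, origin)
    count = int(np.nansum(np.where(zmask, mask_grid, 0)))
    frac = count * res_m * res_m / polygon.area
    return float(min(1.0, max(0.0, frac)))
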