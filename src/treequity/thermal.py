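"""Summer surface-temperature compositing at 30 m.

Scenes carry per-pixel surface temperature in Kelvin plus a QA integer band
in which bit 5 flags cloud and bit 2 cloud shadow.  The composite is the
per-pixel median (mean of the two middle values for even counts) of unmasked
observations across scenes dated inside the summer window, converted to
degrees Celsius; pixels with zero unmasked observations become NaN.
Permanent/seasonal water is removed with a static water mask.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry.base import BaseGeometry

from .rasters import zonal_mean

__all__ = [
    "ThermalScene",
    "ThermalStack",
    "mask_scene",
    "summer_median",
    "zonal_temperature",
    "SUMMER_WINDOW",
]

QA_CLOUD_BIT = 5
QA_SHADOW_BIT = 2
KELVIN_OFFSET = 273.15

# (month, day) endpoints, both inclusive
SUMMER_WINDOW = ((6, 21), (9, 22))


@dataclass
class ThermalScene:
    temp_k: np.ndarray  # (H, W) surface temperature, Kelvin
    qa: np.ndarray  # (H, W) integer QA band
    date: datetime.date

    def __post_init__(self):
        if self.temp_k.shape != self.qa.shape:
            raise ValueError("temperature and QA grids must be co-registered")


@dataclass
class ThermalStack:
    scenes: list[ThermalScene]
    water_mask: np.ndarray  # (H, W) bool, True = water
    res_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)


def mask_scene(scene: ThermalScene, water_mask: np.ndarray | None = None) -> np.ndarray:
    """Temperature grid with cloud (bit 5), shadow (bit 2) and water as NaN."""
    bad = (scene.qa & ((1 << QA_CLOUD_BIT) | (1 << QA_SHADOW_BIT))) != 0
    out = scene.temp_k.astype(float).copy()
    out[bad] = np.nan
    if water_mask is not None:
        out[water_mask.astype(bool)] = np.nan
    return out


def _in_window(date: datetime.date, window=SUMMER_WINDOW, years=None) -> bool:
    if years is not None and date.year not in years:
        return False
    (m0, d0), (m1, d1) = window
    return (date.month, date.day) >= (m0, d0) and (date.month, date.day) <= (m1, d1)


def summer_median(
    stack: ThermalStack,
    window=SUMMER_WINDOW,
    years=None,
) -> np.ndarray:
    """Per-pixel median summer temperature in degrees Celsius.

    Scenes dated outside the (inclusive) window, or outside ``years`` if
    given, are dropped before compositing.
    """
    if not stack.scenes:
        raise ValueError("empty thermal stack")
    kept = [s for s in stack.scenes if _in_window(s.date, window, years)]
    if not kept:
        raise ValueError("no scenes inside the summer window")
    cube = np.stack([mask_scene(s, stack.water_mask) for s in kept])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN pixels
        med = np.nanmedian(cube, axis=0)
    return med - KELVIN_OFFSET


def zonal_temperature(
    temp_grid_c: np.ndarray,
    polygon: BaseGeometry,
    res_m: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Mean composite temperature over pixels whose centers fall in the block.

    Returns NaN (with a warning) if no finite pixel center lies inside.
    """
    val = zonal_mean(temp_grid_c, res_m, polygon, origin)
    if np.isnan(val):
        warnings.warn("zone has no unmasked thermal pixels; temperature missing")
    return val
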