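"""Census-block selection, income linking and block-level canopy/temperature.

Analysis blocks are those lying entirely inside the urbanized-area boundary
buffered out 100 m (absorbing slight boundary misalignment) and having at
least one resident.  Per-capita income is published at block-group level and
attaches to blocks by centroid containment; where a block-group estimate is
unreliable (coefficient of variation SE/estimate above 34%) the parent
tract's estimate is used instead.  Block canopy fraction and temperature use
the pixel-center zonal convention shared with the thermal module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

from .rasters import zonal_fraction

__all__ = [
    "select_blocks",
    "link_income",
    "block_canopy_fraction",
    "population_density",
    "attach_canopy",
]

CV_THRESHOLD = 0.34


def select_blocks(
    blocks: pd.DataFrame, ua_boundary: BaseGeometry, buffer_m: float = 100.0
) -> pd.DataFrame:
    """Retain blocks fully within the buffered UA boundary with population > 0."""
    for bid, geom in zip(blocks["block_id"], blocks["geometry"]):
        if geom is None or not geom.is_valid:
            raise ValueError(f"invalid geometry for block {bid}")
    buffered = ua_boundary.buffer(buffer_m)
    inside = np.array([geom.within(buffered) for geom in blocks["geometry"]])
    populated = blocks["population"].to_numpy() > 0
    return blocks.loc[inside & populated].reset_index(drop=True)


def link_income(
    blocks: pd.DataFrame,
    block_groups: pd.DataFrame,
    cv_threshold: float = CV_THRESHOLD,
) -> pd.DataFrame:
    """Attach per-capita income to blocks via block-group centroid lookup.

    Uses the block-group estimate unless SE/estimate > ``cv_threshold``
    (strict inequality: CV exactly at the threshold keeps the block-group
    value), in which case the parent tract's estimate is substituted.
    ``income_source`` records which level supplied each value.
    """
    geoms = list(block_groups["geometry"])
    tree = STRtree(geoms)
    est = block_groups["income_per_capita"].to_numpy(dtype=float)
    se = block_groups["standard_error"].to_numpy(dtype=float)
    tract = block_groups["parent_tract_income"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(est > 0, se / est, np.inf)
    use_tract = cv > cv_threshold
    bg_value = np.where(use_tract, tract, est)
    bg_source = np.where(use_tract, "tract", "block_group")

    incomes = np.empty(len(blocks))
    sources = np.empty(len(blocks), dtype=object)
    for k, geom in enumerate(blocks["geometry"]):
        c = geom.centroid
        hits = tree.query(c, predicate="intersects")
        if len(hits) == 0:
            raise ValueError(
                f"block {blocks['block_id'].iloc[k]} centroid falls in no block group"
            )
        g = int(hits[0])
        incomes[k] = bg_value[g]
        sources[k] = bg_source[g]
    out = blocks.copy()
    out["income_per_capita"] = incomes
    out["income_source"] = sources
    return out


def block_canopy_fraction(
    canopy_mask: np.ndarray,
    polygon: BaseGeometry,
    res_m: float = 2.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Tree-cover fraction of one block from the classified mask.

    (tree pixels with centers inside) * pixel area / block area, in [0, 1].
    Nodata pixels (255) count as not-tree.
    """
    grid = np.where(canopy_mask == 1, 1, 0)
    return zonal_fraction(grid, res_m, polygon, origin)


def attach_canopy(
    blocks: pd.DataFrame,
    canopy_mask: np.ndarray,
    res_m: float = 2.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Add a ``canopy_fraction`` column computed per block geometry."""
    out = blocks.copy()
    out["canopy_fraction"] = [
        block_canopy_fraction(canopy_mask, geom, res_m, origin) for geom in blocks["geometry"]
    ]
    return out


def population_density(blocks: pd.DataFrame) -> pd.Series:
    """People per km2: population / (land_area_m2 / 1e6)."""
    area = blocks["land_area_m2"].to_numpy(dtype=float)
    if (area <= 0).any():
        bad = blocks.loc[area <= 0, "block_id"].iloc[0]
        raise ValueError(f"zero land area for block {bad}")
    return pd.Series(
        blocks["population"].to_numpy(dtype=float) / (area / 1e6),
        index=blocks.index,
        name="density",
    )
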