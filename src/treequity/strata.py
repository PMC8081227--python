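"""Income/density stratification and population-weighted medians.

Blocks are cut into per-capita-income quartiles *within each urbanized
area* (block-count quartiles; incomes differ enormously between UAs) and
into four fixed population-density classes: Very Low [0, 2000), Low
[2000, 4000), Moderate [4000, 8000) and High [8000, inf) people/km2.
Cell summaries use the population-weighted median: the smallest value at
which cumulative block population reaches half the total, i.e. the tree
cover or temperature experienced by the "median person", not the median
block of land.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DENSITY_CATEGORIES",
    "income_quartiles",
    "density_category",
    "weighted_median",
    "majority_white",
    "income_percentile_curve",
    "summary_table",
    "ua_level_table",
]

DENSITY_BREAKS = (2000.0, 4000.0, 8000.0)
DENSITY_CATEGORIES = ("VeryLow", "Low", "Moderate", "High")


def income_quartiles(blocks: pd.DataFrame) -> pd.Series:
    """Quartile labels 1-4 by block-count rank of income within one UA.

    Ties are resolved deterministically by stable ordering on block_id, so
    duplicated incomes at a quartile boundary split reproducibly.
    """
    if blocks["ua_id"].nunique() > 1:
        raise ValueError("income_quartiles operates on the blocks of one UA")
    income = blocks["income_per_capita"].to_numpy(dtype=float)
    n = len(income)
    if n < 4:
        raise ValueError("need at least 4 blocks to form quartiles")
    if np.ptp(income) == 0:
        raise ValueError("degenerate stratification: all incomes equal")
    order = np.lexsort((blocks["block_id"].to_numpy(), income))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    q = np.minimum(rank * 4 // n, 3) + 1
    return pd.Series(q, index=blocks.index, name="income_quartile")


def density_category(density) -> np.ndarray:
    """Half-open density bins [0,2000), [2000,4000), [4000,8000), [8000,inf)."""
    d = np.asarray(density, dtype=float)
    if (d < 0).any():
        raise ValueError("negative population density")
    idx = np.digitize(d, DENSITY_BREAKS)  # boundary value goes up a class
    return np.array(DENSITY_CATEGORIES, dtype=object)[idx]


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total.

    Lower-value rule at the 50% crossing, no interpolation; with unit
    weights this is the lower-middle convention for even counts.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    if w.sum() <= 0:
        raise ValueError("all weights are zero")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    k = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(v[k])


def majority_white(blocks: pd.DataFrame) -> pd.Series:
    """1 iff strictly more than half of residents are non-Hispanic white."""
    pop = blocks["population"].to_numpy(dtype=float)
    white = blocks["n_nonhisp_white"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        flag = np.where(pop > 0, white / pop > 0.5, False)
    return pd.Series(flag.astype(int), index=blocks.index, name="majority_white")


def _income_percentile(blocks: pd.DataFrame) -> pd.Series:
    """Within-UA income percentile in [0, 100) by block-count rank."""
    out = pd.Series(np.nan, index=blocks.index, name="income_percentile")
    for _, grp in blocks.groupby("ua_id"):
        income = grp["income_per_capita"].to_numpy(dtype=float)
        order = np.lexsort((grp["block_id"].to_numpy(), income))
        rank = np.empty(len(income), dtype=float)
        rank[order] = np.arange(len(income))
        out.loc[grp.index] = (rank + 0.5) / len(income) * 100.0
    return out


def income_percentile_curve(blocks: pd.DataFrame, bin_pct: float = 5.0) -> pd.DataFrame:
    """Weighted-median canopy per income-percentile bin across the study area.

    Percentiles are computed within each UA first, then pooled into
    ``100/bin_pct`` bins; the population-weighted median canopy percent is
    reported per bin.  Empty bins yield missing points.
    """
    if len(blocks) < 20:
        raise ValueError("need at least 20 blocks for a percentile curve")
    pct = _income_percentile(blocks)
    edges = np.arange(0.0, 100.0 + bin_pct, bin_pct)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (pct >= lo) & (pct < hi)
        if not sel.any() or blocks.loc[sel, "population"].sum() == 0:
            continue
        med = weighted_median(
            blocks.loc[sel, "canopy_fraction"] * 100.0, blocks.loc[sel, "population"]
        )
        rows.append({"pct_lo": lo, "pct_hi": hi, "median_canopy_pct": med})
    return pd.DataFrame(rows)


def _prepare(blocks: pd.DataFrame) -> pd.DataFrame:
    df = blocks.copy()
    if "density" not in df:
        df["density"] = df["population"] / (df["land_area_m2"] / 1e6)
    if "density_category" not in df:
        df["density_category"] = density_category(df["density"])
    if "income_quartile" not in df:
        df["income_quartile"] = pd.concat(
            [income_quartiles(g) for _, g in df.groupby("ua_id")]
        ).reindex(df.index)
    return df


def summary_table(blocks: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Stratified summary: weighted-median canopy %, temperature, population
    and land area per (ua_id, income_quartile, density_category) cell, plus
    per-UA marginals (density_category = "All").

    ``mode="pooled"`` (default) also emits study-wide rows (ua_id = "ALL")
    pooling blocks across UAs; ``mode="per_ua_mean"`` emits study-wide rows
    that average the per-UA cell medians instead.
    """
    df = _prepare(blocks)
    has_temp = "temperature_c" in df and df["temperature_c"].notna().any()

    def cell(grp) -> dict:
        d = {
            "median_canopy_pct": weighted_median(
                grp["canopy_fraction"] * 100.0, grp["population"]
            ),
            "population": int(grp["population"].sum()),
            "land_area_m2": float(grp["land_area_m2"].sum()),
            "n_blocks": len(grp),
        }
        if has_temp:
            ok = grp["temperature_c"].notna()
            d["median_temp_c"] = (
                weighted_median(grp.loc[ok, "temperature_c"], grp.loc[ok, "population"])
                if ok.any() and grp.loc[ok, "population"].sum() > 0
                else np.nan
            )
        return d

    rows = []
    for (ua, q, dc), grp in df.groupby(["ua_id", "income_quartile", "density_category"]):
        rows.append({"ua_id": ua, "income_quartile": q, "density_category": dc, **cell(grp)})
    for (ua, q), grp in df.groupby(["ua_id", "income_quartile"]):
        rows.append({"ua_id": ua, "income_quartile": q, "density_category": "All", **cell(grp)})
    if df["ua_id"].nunique() > 1 or mode != "pooled":
        if mode == "pooled":
            for (q, dc), grp in df.groupby(["income_quartile", "density_category"]):
                rows.append(
                    {"ua_id": "ALL", "income_quartile": q, "density_category": dc, **cell(grp)}
                )
            for q, grp in df.groupby("income_quartile"):
                rows.append(
                    {"ua_id": "ALL", "income_quartile": q, "density_category": "All", **cell(grp)}
                )
        elif mode == "per_ua_mean":
            base = pd.DataFrame(rows)
            sub = base[base["ua_id"] != "ALL"]
            for (q, dc), grp in sub.groupby(["income_quartile", "density_category"]):
                rows.append(
                    {
                        "ua_id": "ALL",
                        "income_quartile": q,
                        "density_category": dc,
                        "median_canopy_pct": float(grp["median_canopy_pct"].mean()),
                        "population": int(grp["population"].sum()),
                        "land_area_m2": float(grp["land_area_m2"].sum()),
                        "n_blocks": int(grp["n_blocks"].sum()),
                        **(
                            {"median_temp_c": float(grp["median_temp_c"].mean())}
                            if has_temp
                            else {}
                        ),
                    }
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def ua_level_table(blocks: pd.DataFrame, ua_coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per UA: inputs for the among-UA regressions.

    median_canopy (fraction), q1/q4 weighted-median canopy and their gap,
    median/IQR income, median/IQR density, biome, and coordinates if given.
    """
    df = _prepare(blocks)
    rows = []
    for ua, grp in df.groupby("ua_id"):
        inc = grp["income_per_capita"]
        den = grp["density"]
        q1 = grp[grp["income_quartile"] == 1]
        q4 = grp[grp["income_quartile"] == 4]
        med = weighted_median(grp["canopy_fraction"], grp["population"])
        m1 = weighted_median(q1["canopy_fraction"], q1["population"])
        m4 = weighted_median(q4["canopy_fraction"], q4["population"])
        rows.append(
            {
                "ua_id": ua,
                "median_canopy": med,
                "q1_canopy": m1,
                "q4_canopy": m4,
                "canopy_gap": m4 - m1,
                "median_income": float(inc.median()),
                "iqr_income": float(inc.quantile(0.75) - inc.quantile(0.25)),
                "median_density": float(den.median()),
                "iqr_density": float(den.quantile(0.75) - den.quantile(0.25)),
                "biome": grp["biome"].iloc[0] if "biome" in grp else "unknown",
            }
        )
    out = pd.DataFrame(rows)
    if ua_coords is not None:
        out = out.merge(ua_coords[["ua_id", "x_m", "y_m"]], on="ua_id", how="left")
    return out
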