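"""Tree-cover disparity accounting.

The disparity is a policy-facing quantity: within each population-density
class of each urbanized area, how much canopy area would have to be added to
low-income (bottom-quartile) blocks to raise their population-weighted
median tree cover to that of high-income (top-quartile) blocks of the same
density class.  Canopy area converts to tree counts at 19.6 m2 of canopy per
urban tree (a national average: 5.5e9 urban trees over 67.6e6 acres at 39.3%
mean cover), tree counts to planting cost at $283 per stem, and to
compensatory value — what owners would be owed if the trees were lost — at
per-stem appraisal values.

Negative per-cell disparities (low-income blocks greener than high-income
ones) are floored at zero by default before aggregation: a surplus in one
city cannot offset a deficit in another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValuationConstants",
    "SQM_PER_ACRE",
    "canopy_per_tree",
    "disparity_cells",
    "aggregate_ledger",
    "trees_required",
    "planting_cost",
    "compensatory_value",
    "per_person_value",
    "REFERENCE_NATIONAL_TABLE",
    "verify_reference_arithmetic",
]

SQM_PER_ACRE = 4046.8564224


@dataclass(frozen=True)
class ValuationConstants:
    """Per-tree conversion and valuation factors (nominal USD)."""

    canopy_per_tree_m2: float = 19.6
    planting_usd_per_stem: float = 283.0
    compensatory_usd_per_stem_median: float = 904.4
    compensatory_usd_per_stem_low: float = 653.8
    compensatory_usd_per_stem_high: float = 1812.1

    def __post_init__(self):
        for name in (
            "canopy_per_tree_m2",
            "planting_usd_per_stem",
            "compensatory_usd_per_stem_median",
            "compensatory_usd_per_stem_low",
            "compensatory_usd_per_stem_high",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def canopy_per_tree(n_trees: float, urban_acres: float, mean_cover_fraction: float) -> float:
    """m2 of canopy per urban tree: acres * 4046.8564 * cover / trees."""
    if n_trees <= 0:
        raise ValueError("tree count must be positive")
    if urban_acres <= 0 or mean_cover_fraction <= 0:
        raise ValueError("area and cover must be positive")
    return urban_acres * SQM_PER_ACRE * mean_cover_fraction / n_trees


def trees_required(needed_canopy_m2: float, constants: ValuationConstants) -> int:
    """Adult trees needed to supply the canopy area, rounded to nearest."""
    if needed_canopy_m2 < 0:
        raise ValueError("needed canopy area must be >= 0")
    return int(round(needed_canopy_m2 / constants.canopy_per_tree_m2))


def planting_cost(trees: int, constants: ValuationConstants) -> float:
    """Sapling planting cost in USD."""
    if trees < 0:
        raise ValueError("tree count must be >= 0")
    return trees * constants.planting_usd_per_stem


def compensatory_value(trees: int, constants: ValuationConstants) -> dict[str, float]:
    """Compensatory (appraisal) value in USD: median, low, high."""
    if trees < 0:
        raise ValueError("tree count must be >= 0")
    return {
        "median": trees * constants.compensatory_usd_per_stem_median,
        "low": trees * constants.compensatory_usd_per_stem_low,
        "high": trees * constants.compensatory_usd_per_stem_high,
    }


def per_person_value(total_usd: float, total_population: float) -> float:
    """USD per resident, rounded to the nearest dollar."""
    if total_population <= 0:
        raise ValueError("population must be positive")
    return float(round(total_usd / total_population))


def disparity_cells(
    summary: pd.DataFrame, floor_at_zero: bool = True
) -> pd.DataFrame:
    """Per-(UA, density-category) disparity and needed canopy area.

    ``summary`` is the stratified table (one row per UA x quartile x density
    cell with weighted-median canopy %, population and land area).  For each
    UA and density category present in both quartile 1 and 4:

        disparity_pct   = median(Q4) - median(Q1), floored at 0 by default
        needed_canopy   = disparity_pct/100 * land area of Q1 blocks
        population      = population of Q1 blocks (the beneficiaries)

    Cells missing either quartile are skipped with a warning.
    """
    import warnings

    cells = summary[
        (summary["density_category"] != "All") & (summary["ua_id"] != "ALL")
    ]
    rows = []
    for (ua, dc), grp in cells.groupby(["ua_id", "density_category"]):
        lo = grp[grp["income_quartile"] == 1]
        hi = grp[grp["income_quartile"] == 4]
        if lo.empty or hi.empty:
            warnings.warn(f"skipping cell ({ua}, {dc}): missing an income quartile")
            continue
        disp = float(hi["median_canopy_pct"].iloc[0] - lo["median_canopy_pct"].iloc[0])
        if floor_at_zero:
            disp = max(0.0, disp)
        area_lo = float(lo["land_area_m2"].iloc[0])
        rows.append(
            {
                "ua_id": ua,
                "density_category": dc,
                "disparity_pct": disp,
                "low_income_area_m2": area_lo,
                "low_income_population": int(lo["population"].iloc[0]),
                "needed_canopy_m2": disp / 100.0 * area_lo,
            }
        )
    return pd.DataFrame(rows)


def aggregate_ledger(
    cells: pd.DataFrame, constants: ValuationConstants | None = None
) -> pd.DataFrame:
    """Roll the per-(UA, density) cells up into the disparity ledger.

    Returns one row per density category plus a ``Total`` row, with needed
    canopy, tree counts, planting cost, compensatory values (median, low,
    high) and per-person value over the low-income population.
    """
    if constants is None:
        constants = ValuationConstants()
    order = ["VeryLow", "Low", "Moderate", "High"]
    rows = []
    groups = [(dc, cells[cells["density_category"] == dc]) for dc in order]
    groups.append(("Total", cells))
    for dc, grp in groups:
        if grp.empty:
            continue
        needed = float(grp["needed_canopy_m2"].sum())
        area = float(grp["low_income_area_m2"].sum())
        pop = int(grp["low_income_population"].sum())
        trees = trees_required(needed, constants)
        comp = compensatory_value(trees, constants)
        rows.append(
            {
                "density_category": dc,
                "low_income_area_m2": area,
                "low_income_population": pop,
                "disparity_pct": 100.0 * needed / area if area > 0 else np.nan,
                "needed_canopy_m2": needed,
                "trees_required": trees,
                "planting_cost_usd": planting_cost(trees, constants),
                "compensatory_usd_median": comp["median"],
                "compensatory_usd_low": comp["low"],
                "compensatory_usd_high": comp["high"],
                "per_person_usd": per_person_value(comp["median"], pop) if pop > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# published national reference table (used only as an arithmetic cross-check)
# --------------------------------------------------------------------------

# National tree-cover disparity accounting by population-density category,
# as published for the 100 largest US urbanized areas.  Used by
# verify_reference_arithmetic to confirm that this package's conversion
# chain (areas -> trees -> costs -> per-person values) reproduces the
# printed cells from the printed inputs.
REFERENCE_NATIONAL_TABLE = pd.DataFrame(
    {
        "density_category": ["VeryLow", "Low", "Moderate", "High", "Total"],
        "low_income_area_km2": [12_528, 3_656, 1_816, 905, 18_906],
        "low_income_population": [8_120_985, 10_431_696, 9_863_540, 13_326_870, 41_743_091],
        "disparity_pct": [9.8, 3.7, 2.6, 3.3, 4.9],
        "needed_canopy_km2": [985, 171, 50, 11, 1_217],
        "trees_required": [50_367_030, 8_762_004, 2_547_062, 575_105, 62_251_201],
        "compensatory_billions_median": [45.5, 7.9, 2.3, 0.5, 56.3],
        "compensatory_billions_low": [32.9, 5.7, 1.7, 0.4, 40.7],
        "compensatory_billions_high": [91.3, 15.9, 4.6, 1.0, 112.8],
        "planting_billions": [14.3, 2.5, 0.7, 0.2, 17.6],
    }
)

# national derivation inputs for the canopy-per-tree factor
REFERENCE_TREE_STOCK = {
    "n_trees": 5.5e9,
    "urban_acres": 67.6e6,
    "mean_cover_fraction": 0.393,
}


def verify_reference_arithmetic(constants: ValuationConstants | None = None) -> pd.DataFrame:
    """Recompute the published disparity chain from its printed inputs.

    For every density category: trees from printed needed-canopy areas
    (expected within 0.5%, since printed km2 are rounded), planting cost and
    compensatory values from printed tree counts (expected to match at the
    printed one-decimal billions), the national needed-canopy sum, and the
    per-person value from the printed national compensatory total and
    low-income population.  Returns a tidy report with one row per check.
    """
    if constants is None:
        constants = ValuationConstants()
    ref = REFERENCE_NATIONAL_TABLE
    rows = []
    for _, r in ref.iterrows():
        dc = r["density_category"]
        trees_hat = trees_required(r["needed_canopy_km2"] * 1e6, constants)
        rel = abs(trees_hat - r["trees_required"]) / r["trees_required"]
        # published areas are printed to the km2; allow that rounding plus 0.5%
        tol = 0.5 / r["needed_canopy_km2"] + 0.005
        rows.append(
            {
                "check": f"trees_from_area[{dc}]",
                "computed": trees_hat,
                "published": r["trees_required"],
                "agrees": rel <= tol,
            }
        )
        cost_b = round(planting_cost(int(r["trees_required"]), constants) / 1e9, 1)
        rows.append(
            {
                "check": f"planting_billions[{dc}]",
                "computed": cost_b,
                "published": r["planting_billions"],
                "agrees": cost_b == r["planting_billions"],
            }
        )
        comp = compensatory_value(int(r["trees_required"]), constants)
        for key, col in (
            ("median", "compensatory_billions_median"),
            ("low", "compensatory_billions_low"),
            ("high", "compensatory_billions_high"),
        ):
            v = round(comp[key] / 1e9, 1)
            rows.append(
                {
                    "check": f"compensatory_{key}_billions[{dc}]",
                    "computed": v,
                    "published": r[col],
                    # per-stem values are back-computed from the printed
                    # national totals, so per-category cells can differ by
                    # one unit of printed precision (0.1 B)
                    "agrees": abs(v - r[col]) <= 0.1 + 1e-9,
                }
            )
    cat = ref[ref["density_category"] != "Total"]
    tot = ref[ref["density_category"] == "Total"].iloc[0]
    ssum = int(cat["needed_canopy_km2"].sum())
    rows.append(
        {
            "check": "needed_canopy_sum_km2",
            "computed": ssum,
            "published": int(tot["needed_canopy_km2"]),
            "agrees": ssum == int(tot["needed_canopy_km2"]),
        }
    )
    ppv = per_person_value(tot["compensatory_billions_median"] * 1e9, tot["low_income_population"])
    rows.append({"check": "per_person_usd", "computed": ppv, "published": 1349, "agrees": ppv == 1349})
    cpt = canopy_per_tree(**REFERENCE_TREE_STOCK)
    rows.append(
        {
            "check": "canopy_per_tree_m2",
            "computed": round(cpt, 2),
            "published": constants.canopy_per_tree_m2,
            "agrees": abs(cpt - constants.canopy_per_tree_m2) / constants.canopy_per_tree_m2
            <= 0.005,
        }
    )
    return pd.DataFrame(rows)
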