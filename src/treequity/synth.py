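"""Synthetic city generator.

Builds planar "cities" with known ground truth that emulate the statistical
structure the tree-equity analysis assumes: a 2 m four-band (B, G, R, NIR)
image whose classes are tree / grass / impervious / soil / water; a stack of
30 m thermal scenes in Kelvin with QA cloud/shadow bits and a water mask; and
nested census block / block-group vector tables carrying population, race
counts, median age, block-group per-capita income (with standard errors) and
built-up intensity.

The generator's dials are the assumptions under test: a configurable
association between income percentile and block canopy fraction
(``beta_income_canopy``), a canopy decline across population-density classes
(``density_decay``), a spatial correlation range for the canopy field, a
bimodal race composition, and a linear surface-temperature response to local
canopy (``temp_per_canopy``, degC per unit canopy fraction).

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawns, one child stream per sub-generator, so that e.g. regenerating the
thermal stack does not perturb the imagery.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .rasters import Raster
from .thermal import ThermalScene, ThermalStack

__all__ = [
    "CityConfig",
    "GroundTruth",
    "CLASS_CODES",
    "generate_city",
    "render_imagery",
    "render_thermal_stack",
    "sample_control_points",
    "simulate_block_table",
    "simulate_study",
    "gaussian_field",
]

# categorical land-cover codes used in class_map
CLASS_CODES = {"tree": 1, "grass": 2, "impervious": 3, "soil": 4, "water": 5}

# mean reflectance per class for bands (B, G, R, NIR), plus a per-class noise
# scale.  Trees and grass share high NIR/NDVI; trees additionally receive
# strong per-pixel NIR/R speckle (sunlit crowns vs internal shadow) so their
# local NDVI heterogeneity -- and hence GLCM entropy -- is high while grass
# stays smooth.  Water has G > NIR (NDWI > 0); impervious has NIR ~ R
# (NDVI ~ 0).
_REFLECTANCE = {
    "tree": (0.05, 0.09, 0.06, 0.42),
    "grass": (0.06, 0.12, 0.08, 0.45),
    "impervious": (0.18, 0.18, 0.19, 0.20),
    "soil": (0.12, 0.15, 0.20, 0.28),
    "water": (0.08, 0.07, 0.05, 0.02),
}
_CLASS_NOISE = {"tree": 0.01, "grass": 0.01, "impervious": 0.015, "soil": 0.015, "water": 0.005}
# extra heterogeneity on (R, NIR) for tree crowns
_TREE_SPECKLE = (0.03, 0.12)

_DENSITY_BREAKS = (2000.0, 4000.0, 8000.0)  # people/km2 class edges

QA_CLOUD_BIT = 5
QA_SHADOW_BIT = 2


@dataclass(frozen=True)
class CityConfig:
    """Parameters of one synthetic city (a single urbanized area)."""

    grid_extent_m: float = 2400.0
    img_res_m: float = 2.0
    thermal_res_m: float = 30.0
    n_blocks: int = 576
    n_block_groups: int = 36
    n_tracts: int = 9
    total_population: int = 25_000
    income_lognormal_params: tuple[float, float] = (10.3, 0.5)  # mu, sigma of log income
    beta_income_canopy: float = 0.24  # canopy fraction per unit income percentile
    density_decay: float = 0.09  # canopy drop per density class step
    canopy_base: float = 0.45  # canopy at median income, lowest density class
    canopy_noise_sd: float = 0.06
    water_fraction: float = 0.03
    race_bimodal_mix: tuple[float, float] = (0.6, 0.4)  # Beta(8,2) vs Beta(2,8) weights
    race_income_coupling: float = 0.3
    autocorr_range_m: float = 1000.0  # correlation range of the canopy target field
    center_density_scale_m: float = 600.0  # e-folding radius of the density gradient
    center_gradient_income: bool = False  # couple income to distance from center
    temp_baseline_c: float = 30.0
    temp_per_canopy: float = -10.0  # degC per unit canopy fraction (negative cools)
    temp_noise_sd: float = 0.3
    scene_offset_sd: float = 2.0  # K, scene-to-scene weather offset
    scene_pixel_noise_sd: float = 0.5  # K
    cloud_fraction: float = 0.3
    n_scenes: int = 12
    income_nugget: float = 0.5  # iid share of income-field variance (survey noise)
    cv_exceed_frac: float = 0.1  # share of block groups with income CV > 0.34
    ua_id: str = "UA001"
    biome: str = "temperate_broadleaf"
    seed: int = 0

    def __post_init__(self):
        for name in ("beta_income_canopy",):
            pass
        for name in ("water_fraction", "cloud_fraction", "cv_exceed_frac", "canopy_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.race_bimodal_mix) - 1.0) > 1e-9:
            raise ValueError("race_bimodal_mix must sum to 1")
        for res in (self.img_res_m, self.thermal_res_m):
            if abs(self.grid_extent_m / res - round(self.grid_extent_m / res)) > 1e-9:
                raise ValueError(f"resolution {res} must divide extent {self.grid_extent_m}")
        if self.n_block_groups > self.n_blocks:
            raise ValueError("n_block_groups must be <= n_blocks")
        if self.n_tracts > self.n_block_groups:
            raise ValueError("n_tracts must be <= n_block_groups")
        nbx, nby = _grid_factor(self.n_blocks)
        bw = self.grid_extent_m / nbx
        if bw < self.img_res_m or self.grid_extent_m / nby < self.img_res_m:
            raise ValueError(
                f"infeasible geometry: {self.n_blocks} blocks do not fit a "
                f"{self.grid_extent_m} m extent at {self.img_res_m} m resolution"
            )

    @property
    def img_shape(self) -> tuple[int, int]:
        n = int(round(self.grid_extent_m / self.img_res_m))
        return (n, n)

    @property
    def thermal_shape(self) -> tuple[int, int]:
        n = int(round(self.grid_extent_m / self.thermal_res_m))
        return (n, n)


@dataclass
class GroundTruth:
    """Known truth of a generated city, for oracle checks and validation."""

    canopy_mask: np.ndarray  # (H, W) uint8, 1 = tree, at imagery resolution
    class_map: np.ndarray  # (H, W) uint8, CLASS_CODES values
    block_truth: pd.DataFrame  # block_id, canopy_fraction, mean_temp_c
    temp_truth_c: np.ndarray  # (h, w) float at thermal resolution
    water_mask: np.ndarray  # (h, w) bool at thermal resolution


def _grid_factor(n: int) -> tuple[int, int]:
    """Factor n into the (nx, ny) divisor pair closest to a square."""
    best = None
    for a in range(1, int(np.sqrt(n)) + 1):
        if n % a == 0:
            best = (n // a, a)
    if best is None:  # unreachable: 1 always divides
        raise ValueError(f"cannot factor {n}")
    return best


def gaussian_field(
    shape: tuple[int, int],
    range_m: float,
    res_m: float,
    rng: np.random.Generator,
    sd: float = 1.0,
) -> np.ndarray:
    """Smooth Gaussian random field: white noise filtered at sigma = range/2.

    Standardized to zero mean, standard deviation ``sd`` over the grid.
    """
    white = rng.standard_normal(shape)
    sigma_px = max(range_m / res_m / 2.0, 1e-6)
    f = gaussian_filter(white, sigma=sigma_px, mode="reflect")
    f -= f.mean()
    s = f.std()
    if s > 0:
        f *= sd / s
    return f


def _largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to weights, sum-exact."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _vector_city(config: CityConfig, ss: np.random.SeedSequence):
    """Blocks + block groups with demographics, income and canopy targets.

    Returns (blocks, block_groups, canopy_target) where canopy_target is the
    per-block intended canopy fraction before pixel-level realization.
    """
    seeds = ss.spawn(6)
    rng_pop = np.random.default_rng(seeds[0])
    rng_inc = np.random.default_rng(seeds[1])
    rng_race = np.random.default_rng(seeds[2])
    rng_can = np.random.default_rng(seeds[3])
    rng_age = np.random.default_rng(seeds[4])
    rng_bui = np.random.default_rng(seeds[5])

    ext = config.grid_extent_m
    nbx, nby = _grid_factor(config.n_blocks)
    bw, bh = ext / nbx, ext / nby
    bj, bi = np.meshgrid(np.arange(nbx), np.arange(nby))
    bj, bi = bj.ravel(), bi.ravel()
    cx = (bj + 0.5) * bw
    cy = (bi + 0.5) * bh

    # --- population: radial density gradient times a lognormal texture -----
    r = np.hypot(cx - ext / 2, cy - ext / 2)
    w = np.exp(-r / config.center_density_scale_m)
    w = w * np.exp(0.5 * gaussian_field((nby, nbx), bw * 3, bw, rng_pop).ravel())
    population = _largest_remainder_round(w, config.total_population)
    land_area = np.full(config.n_blocks, bw * bh)
    density = population / (land_area / 1e6)
    density_class = np.digitize(density, _DENSITY_BREAKS)

    # --- block-group / tract membership ------------------------------------
    ngx, ngy = _grid_factor(config.n_block_groups)
    gi = (bi * ngy) // nby
    gj = (bj * ngx) // nbx
    bg_index = gi * ngx + gj
    ntx, nty = _grid_factor(config.n_tracts)
    ti = (bi * nty) // nby
    tj = (bj * ntx) // nbx
    tract_index = ti * ntx + tj

    # --- income at block-group level ---------------------------------------
    # A smooth field over the block-group grid (optionally plus a center
    # gradient) sets the income *rank*; the marginal distribution is the
    # configured lognormal.  All blocks of one group share the group value.
    mu, sigma = config.income_lognormal_params
    gfield = gaussian_field((ngy, ngx), config.autocorr_range_m, ext / ngx, rng_inc)
    if config.income_nugget > 0:
        # survey/sampling noise: block-group estimates are far rougher than
        # the underlying wealth surface
        a = config.income_nugget
        gfield = np.sqrt(1 - a) * gfield + np.sqrt(a) * rng_inc.standard_normal(gfield.shape)
    if config.center_gradient_income:
        gjj, gii = np.meshgrid(np.arange(ngx), np.arange(ngy))
        gr = np.hypot((gjj + 0.5) * ext / ngx - ext / 2, (gii + 0.5) * ext / ngy - ext / 2)
        gfield = gfield + 1.5 * (gr / gr.max() - 0.5)
    gvals = gfield.ravel()
    bg_rank = np.argsort(np.argsort(gvals, kind="stable"), kind="stable")
    bg_pct = (bg_rank + 0.5) / len(gvals)
    from scipy.stats import norm

    bg_income = np.exp(mu + sigma * norm.ppf(bg_pct))

    n_bg = config.n_block_groups
    n_exceed = int(round(config.cv_exceed_frac * n_bg))
    cv = rng_inc.uniform(0.05, 0.30, size=n_bg)
    if n_exceed > 0:
        idx = rng_inc.choice(n_bg, size=n_exceed, replace=False)
        cv[idx] = rng_inc.uniform(0.36, 0.60, size=n_exceed)
    bg_se = bg_income * cv

    # tract income: population-weighted mean of member block groups
    bg_of_block = bg_index
    bg_pop = np.bincount(bg_of_block, weights=population, minlength=n_bg)
    tract_of_bg = np.zeros(n_bg, dtype=int)
    for g in range(n_bg):
        members = tract_index[bg_of_block == g]
        tract_of_bg[g] = members[0]
    tract_income = np.zeros(config.n_tracts)
    for t in range(config.n_tracts):
        sel = tract_of_bg == t
        wts = np.maximum(bg_pop[sel], 1)
        tract_income[t] = np.average(bg_income[sel], weights=wts)

    income_block = bg_income[bg_of_block]
    # within-UA income percentile by block count (analysis-side convention)
    pct = (np.argsort(np.argsort(income_block, kind="stable"), kind="stable") + 0.5) / len(
        income_block
    )

    # --- race, age, BUI ------------------------------------------------------
    p_white_comp = np.clip(
        config.race_bimodal_mix[0] + config.race_income_coupling * (pct - 0.5), 0, 1
    )
    comp = rng_race.random(config.n_blocks) < p_white_comp
    p_white = np.where(
        comp, rng_race.beta(8, 2, config.n_blocks), rng_race.beta(2, 8, config.n_blocks)
    )
    n_white = np.minimum(np.round(p_white * population).astype(int), population)
    median_age = np.clip(38 + 4 * (pct - 0.5) + rng_age.normal(0, 6, config.n_blocks), 18, 85)
    bui = np.clip(
        1.4 * density / (density + 4000.0) + rng_bui.lognormal(-2.5, 0.6, config.n_blocks),
        0.01,
        None,
    )

    # --- canopy target -------------------------------------------------------
    noise = gaussian_field((nby, nbx), config.autocorr_range_m, bw, rng_can, config.canopy_noise_sd)
    canopy_target = np.clip(
        config.canopy_base
        + config.beta_income_canopy * (pct - 0.5)
        - config.density_decay * density_class
        + noise.ravel(),
        0.02,
        0.95,
    )

    blocks = pd.DataFrame(
        {
            "block_id": [f"{config.ua_id}-B{k:05d}" for k in range(config.n_blocks)],
            "bg_id": [f"{config.ua_id}-G{g:03d}" for g in bg_of_block],
            "tract_id": [f"{config.ua_id}-T{t:02d}" for t in tract_index],
            "ua_id": config.ua_id,
            "biome": config.biome,
            "cx": cx,
            "cy": cy,
            "land_area_m2": land_area,
            "population": population,
            "n_nonhisp_white": n_white,
            "median_age": median_age,
            "bui": bui,
        }
    )
    blocks["geometry"] = [
        box(j * bw, i * bh, (j + 1) * bw, (i + 1) * bh) for i, j in zip(bi, bj)
    ]
    block_groups = pd.DataFrame(
        {
            "bg_id": [f"{config.ua_id}-G{g:03d}" for g in range(n_bg)],
            "tract_id": [f"{config.ua_id}-T{t:02d}" for t in tract_of_bg],
            "income_per_capita": bg_income,
            "standard_error": bg_se,
            "parent_tract_income": tract_income[tract_of_bg],
        }
    )
    gw, gh = ext / ngx, ext / ngy
    block_groups["geometry"] = [
        box((g % ngx) * gw, (g // ngx) * gh, (g % ngx + 1) * gw, (g // ngx + 1) * gh)
        for g in range(n_bg)
    ]
    return blocks, block_groups, canopy_target


def _realize_class_map(
    config: CityConfig,
    blocks: pd.DataFrame,
    canopy_target: np.ndarray,
    ss: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-level class map honoring per-block canopy targets.

    Trees are placed by thresholding a short-range "crown" field at each
    block's target quantile, so canopy is spatially clumped rather than salt
    and pepper.  Water blobs override trees; the remaining pixels split into
    impervious / soil / grass with an impervious share that grows with the
    block's density class.
    """
    seeds = ss.spawn(3)
    rng_place = np.random.default_rng(seeds[0])
    rng_water = np.random.default_rng(seeds[1])
    rng_cls = np.random.default_rng(seeds[2])
    h, w = config.img_shape
    res = config.img_res_m

    crown = gaussian_field((h, w), 24.0, res, rng_place)
    class_map = np.zeros((h, w), dtype=np.uint8)

    nbx, nby = _grid_factor(config.n_blocks)
    bw_px = w // nbx
    bh_px = h // nby
    k = 0
    for i in range(nby):
        for j in range(nbx):
            view = crown[i * bh_px : (i + 1) * bh_px, j * bw_px : (j + 1) * bw_px]
            f = canopy_target[k]
            thr = np.quantile(view, 1.0 - f)
            class_map[i * bh_px : (i + 1) * bh_px, j * bw_px : (j + 1) * bw_px] = np.where(
                view > thr, CLASS_CODES["tree"], 0
            )
            k += 1

    if config.water_fraction > 0:
        wfield = gaussian_field((h, w), 400.0, res, rng_water)
        wthr = np.quantile(wfield, 1.0 - config.water_fraction)
        class_map[wfield > wthr] = CLASS_CODES["water"]

    # remaining pixels: impervious share by density class, small soil share
    u = rng_cls.random((h, w))
    u = gaussian_filter(u, sigma=30.0 / res / 2, mode="reflect")
    u = (np.argsort(np.argsort(u.ravel(), kind="stable"), kind="stable") + 0.5).reshape(h, w)
    u /= u.size  # uniformized, spatially coherent
    p_imp_by_class = np.array([0.15, 0.35, 0.55, 0.75])
    density = blocks["population"].to_numpy() / (blocks["land_area_m2"].to_numpy() / 1e6)
    dclass = np.digitize(density, _DENSITY_BREAKS)
    k = 0
    p_soil = 0.08
    for i in range(nby):
        for j in range(nbx):
            sl = np.s_[i * bh_px : (i + 1) * bh_px, j * bw_px : (j + 1) * bw_px]
            free = class_map[sl] == 0
            p_imp = p_imp_by_class[dclass[k]]
            cell = class_map[sl]
            uu = u[sl]
            cell[free & (uu < p_imp)] = CLASS_CODES["impervious"]
            cell[free & (uu > 1.0 - p_soil)] = CLASS_CODES["soil"]
            cell[cell == 0] = CLASS_CODES["grass"]
            class_map[sl] = cell
            k += 1

    canopy_mask = (class_map == CLASS_CODES["tree"]).astype(np.uint8)
    return class_map, canopy_mask


def render_imagery(
    class_map: np.ndarray, config: CityConfig, rng: np.random.Generator | None = None
) -> Raster:
    """Render a 4-band (B, G, R, NIR) reflectance image from a class map."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    known = set(CLASS_CODES.values())
    present = set(np.unique(class_map).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown class labels in class_map: {sorted(unknown)}")
    h, w = class_map.shape
    bands = np.zeros((4, h, w), dtype=np.float32)
    for cname, code in CLASS_CODES.items():
        sel = class_map == code
        if not sel.any():
            continue
        refl = _REFLECTANCE[cname]
        ns = _CLASS_NOISE[cname]
        n = int(sel.sum())
        for b in range(4):
            bands[b][sel] = refl[b] + rng.normal(0, ns, n)
        if cname == "tree":
            # crown speckle on R and NIR drives local NDVI heterogeneity
            bands[2][sel] += rng.normal(0, _TREE_SPECKLE[0], n)
            bands[3][sel] += rng.normal(0, _TREE_SPECKLE[1], n)
    bands += rng.normal(0, 0.01, bands.shape).astype(np.float32)  # sensor noise
    np.clip(bands, 1e-3, 1.0, out=bands)
    return Raster(
        data=bands, res_m=config.img_res_m, band_names=["B", "G", "R", "NIR"], nodata=None
    )


def render_thermal_stack(
    temp_truth_c: np.ndarray,
    config: CityConfig,
    n_scenes: int | None = None,
    rng: np.random.Generator | None = None,
    water_mask: np.ndarray | None = None,
) -> ThermalStack:
    """Thermal scenes = truth (K) + scene offset + pixel noise, with QA bits.

    Cloud blobs set QA bit 5 on roughly 80% of the masked fraction; their
    shifted shadows set bit 2 on the rest.  Acquisition dates are spread over
    Jun 21 - Sep 22 of 2000-2019.
    """
    if n_scenes is None:
        n_scenes = config.n_scenes
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    h, w = temp_truth_c.shape
    if water_mask is None:
        water_mask = np.zeros((h, w), dtype=bool)
    truth_k = temp_truth_c + 273.15
    scenes = []
    years = rng.choice(np.arange(2000, 2020), size=n_scenes, replace=True)
    for s in range(n_scenes):
        offset = rng.normal(0, config.scene_offset_sd)
        temp = truth_k + offset + rng.normal(0, config.scene_pixel_noise_sd, (h, w))
        qa = np.zeros((h, w), dtype=np.uint16)
        cf = config.cloud_fraction
        if cf > 0:
            cfield = gaussian_field((h, w), 300.0, config.thermal_res_m, rng)
            if cf >= 1.0:
                cloud = np.ones((h, w), dtype=bool)
            else:
                cloud = cfield > np.quantile(cfield, 1.0 - 0.8 * cf)
            qa[cloud] |= 1 << QA_CLOUD_BIT
            shadow = np.roll(cloud, shift=(2, 2), axis=(0, 1)) & ~cloud
            if cf < 1.0:
                # trim shadow to ~20% of the masked budget
                want = int(round(0.2 * cf * h * w))
                sh_idx = np.flatnonzero(shadow.ravel())
                if len(sh_idx) > want:
                    drop = rng.permutation(sh_idx)[want:]
                    shadow.ravel()[drop] = False
            qa[shadow] |= 1 << QA_SHADOW_BIT
        doy = int(rng.integers(0, 94))  # days after Jun 21 (window is 94 days)
        date = datetime.date(int(years[s]), 6, 21) + datetime.timedelta(days=doy)
        scenes.append(ThermalScene(temp_k=temp.astype(np.float32), qa=qa, date=date))
    return ThermalStack(
        scenes=scenes,
        water_mask=water_mask,
        res_m=config.thermal_res_m,
        origin=(0.0, 0.0),
    )


def sample_control_points(
    truth: GroundTruth,
    n: int,
    seed: int | np.random.Generator,
    tree_frac: float = 3746 / 9424,
    res_m: float = 2.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Photo-interpreted control-point analog: labeled tree / not-tree points.

    The number of tree points is binomial in ``tree_frac`` (default ~40%,
    the mix of the national photo-interpretation dataset the classifier is
    trained on); points are pixel centers sampled without replacement within
    each class.
    """
    if n < 2:
        raise ValueError("need at least 2 control points")
    mask = truth.canopy_mask
    h, w = mask.shape
    if n > h * w:
        raise ValueError(f"n={n} exceeds pixel count {h * w}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree_idx = np.flatnonzero(mask.ravel() == 1)
    other_idx = np.flatnonzero(mask.ravel() == 0)
    n_tree = int(rng.binomial(n, tree_frac))
    n_tree = min(n_tree, len(tree_idx))
    n_other = min(n - n_tree, len(other_idx))
    n_tree = n - n_other  # reallocate if a pool ran short
    pick_t = rng.choice(tree_idx, size=n_tree, replace=False) if n_tree else np.array([], int)
    pick_o = rng.choice(other_idx, size=n_other, replace=False) if n_other else np.array([], int)
    idx = np.concatenate([pick_t, pick_o])
    labels = np.concatenate([np.ones(n_tree, int), np.zeros(n_other, int)])
    ii, jj = np.unravel_index(idx, (h, w))
    return pd.DataFrame(
        {
            "x": origin[0] + (jj + 0.5) * res_m,
            "y": origin[1] + (ii + 0.5) * res_m,
            "label": labels,
        }
    )


def generate_city(config: CityConfig):
    """Generate one synthetic city.

    Returns ``(imagery, thermal_stack, blocks, block_groups, truth)``:
    a 4-band 2 m Raster, a ThermalStack, the block and block-group tables
    (without canopy/temperature -- the pipeline computes those), and the
    GroundTruth with per-block true canopy fraction and mean temperature.
    """
    ss = np.random.SeedSequence(config.seed)
    s_vec, s_cls, s_tmp, s_img_unused, s_img, s_thm = ss.spawn(6)

    blocks, block_groups, canopy_target = _vector_city(config, s_vec)
    class_map, canopy_mask = _realize_class_map(config, blocks, canopy_target, s_cls)
    imagery = render_imagery(class_map, config, np.random.default_rng(s_img))

    # thermal truth: baseline + response to 30 m local canopy + smooth noise
    rng_tmp = np.random.default_rng(s_tmp)
    th, tw = config.thermal_shape
    f = int(round(config.thermal_res_m / config.img_res_m))
    cell_canopy = canopy_mask.reshape(th, f, tw, f).mean(axis=(1, 3))
    temp_truth_c = (
        config.temp_baseline_c
        + config.temp_per_canopy * cell_canopy
        + gaussian_field((th, tw), 500.0, config.thermal_res_m, rng_tmp, config.temp_noise_sd)
    )
    water_cell = (class_map == CLASS_CODES["water"]).reshape(th, f, tw, f).mean(axis=(1, 3)) > 0.5
    stack = render_thermal_stack(
        temp_truth_c, config, rng=np.random.default_rng(s_thm), water_mask=water_cell
    )

    # per-block truth by exact pixel counting (blocks are grid-aligned)
    nbx, nby = _grid_factor(config.n_blocks)
    h, w = config.img_shape
    bf = canopy_mask.reshape(nby, h // nby, nbx, w // nbx).mean(axis=(1, 3)).ravel()
    # block mean temperature via 30 m pixel centers (zonal convention)
    from .rasters import zonal_mean

    mean_t = np.array(
        [
            zonal_mean(temp_truth_c, config.thermal_res_m, geom)
            for geom in blocks["geometry"]
        ]
    )
    block_truth = pd.DataFrame(
        {
            "block_id": blocks["block_id"],
            "canopy_fraction": bf,
            "mean_temp_c": mean_t,
        }
    )
    truth = GroundTruth(
        canopy_mask=canopy_mask,
        class_map=class_map,
        block_truth=block_truth,
        temp_truth_c=temp_truth_c,
        water_mask=water_cell,
    )
    return imagery, stack, blocks, block_groups, truth


def simulate_block_table(config: CityConfig, measurement_sd: float = 0.0) -> pd.DataFrame:
    """Raster-free city: block table with canopy fraction and temperature.

    Used for statistical simulations (bootstrap calibration, among-UA
    regressions) where realizing imagery would add nothing.  Canopy is the
    generator's target fraction plus optional measurement noise; block
    temperature is baseline + temp_per_canopy * canopy + noise.
    """
    ss = np.random.SeedSequence(config.seed)
    s_vec, _, s_tmp, *_ = ss.spawn(6)
    blocks, block_groups, canopy_target = _vector_city(config, s_vec)
    rng = np.random.default_rng(s_tmp)
    canopy = canopy_target
    if measurement_sd > 0:
        canopy = np.clip(canopy + rng.normal(0, measurement_sd, len(canopy)), 0.0, 1.0)
    blocks = blocks.copy()
    blocks["canopy_fraction"] = canopy
    blocks["temperature_c"] = (
        config.temp_baseline_c
        + config.temp_per_canopy * canopy_target
        + rng.normal(0, config.temp_noise_sd, len(blocks))
    )
    bg_inc = block_groups.set_index("bg_id")["income_per_capita"]
    blocks["income_per_capita"] = blocks["bg_id"].map(bg_inc).to_numpy()
    blocks["income_source"] = "block_group"
    return blocks


def simulate_study(
    n_uas: int,
    seed: int,
    base_config: CityConfig | None = None,
    biomes: tuple[str, ...] = ("temperate_broadleaf", "grassland", "desert"),
    biome_canopy_shift: dict[str, float] | None = None,
    extent_km: float = 3000.0,
    vary: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A multi-city study: concatenated block tables plus UA coordinates.

    Each UA draws its own seed, biome (shifting baseline canopy), and mild
    parameter jitter; UA centroids are scattered over an ``extent_km`` square
    so distance-band spatial weights are meaningful.  Returns
    ``(blocks, ua_table_base)`` where the second frame holds ua_id, x/y (m),
    and biome.
    """
    if base_config is None:
        base_config = CityConfig(n_blocks=144, n_block_groups=16, n_tracts=4, total_population=6000)
    if biome_canopy_shift is None:
        biome_canopy_shift = {"temperate_broadleaf": 0.0, "grassland": -0.15, "desert": -0.3}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    frames = []
    ua_rows = []
    for k in range(n_uas):
        biome = biomes[k % len(biomes)]
        overrides = {
            "ua_id": f"UA{k:03d}",
            "biome": biome,
            "seed": int(rng.integers(0, 2**31 - 1)),
            "canopy_base": float(
                np.clip(
                    base_config.canopy_base
                    + biome_canopy_shift.get(biome, 0.0)
                    + rng.normal(0, 0.03),
                    0.05,
                    0.9,
                )
            ),
            "income_lognormal_params": (
                base_config.income_lognormal_params[0] + float(rng.normal(0, 0.2)),
                base_config.income_lognormal_params[1] * float(np.exp(rng.normal(0, 0.2))),
            ),
        }
        if vary:
            overrides.update({k2: v(rng) if callable(v) else v for k2, v in vary.items()})
        cfg = replace(base_config, **overrides)
        blocks = simulate_block_table(cfg)
        frames.append(blocks)
        ua_rows.append(
            {
                "ua_id": cfg.ua_id,
                "x_m": float(rng.uniform(0, extent_km * 1000)),
                "y_m": float(rng.uniform(0, extent_km * 1000)),
                "biome": biome,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(ua_rows)
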