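"""Tree / not-tree classification of 2 m four-band imagery.

The feature stack has ten co-registered bands: the four reflectance bands
(B, G, R, NIR); three normalized band-ratio indices

    NDVI = (NIR - R) / (NIR + R)
    GNDVI = (NIR - G) / (NIR + G)
    NDWI = (G - NIR) / (G + NIR)

two texture bands derived from the gray-level co-occurrence matrix (GLCM) of
quantized NDVI in a 4x4 moving window (entropy and contrast); and a binary
layer that is 1 where both GLCM entropy and NDVI exceed region-specific
thresholds.  Texture is what separates tree canopy (heterogeneous NDVI:
sunlit crowns and internal shadow) from equally green but smooth surfaces
such as pasture, ballfields, and golf courses.

GLCM parameterization: NDVI is quantized to ``levels`` gray levels over the
scene-wide finite range (so entropy is comparable across windows), pixel
pairs at offset 1 are accumulated symmetrically (both orders), and the
horizontal and vertical directions are computed separately and averaged.
Window entropy is -sum p ln p over co-occurrence cells; contrast is
sum p (i - j)^2.  Edge windows use the pixels actually available.

A random forest over the ten feature values at labeled control points does
the final classification; accuracy is reported from out-of-bag predictions
as a confusion matrix with overall, user's and producer's accuracy for the
tree class and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .rasters import Raster

__all__ = [
    "FeatureStack",
    "RegionThresholds",
    "AccuracyReport",
    "ndvi",
    "gndvi",
    "ndwi",
    "glcm_entropy",
    "glcm_textures",
    "binary_texture_layer",
    "choose_thresholds",
    "apply_thresholds",
    "build_feature_stack",
    "train_classifier",
    "classify",
    "accuracy_from_confusion",
]

FEATURE_BANDS = [
    "B",
    "G",
    "R",
    "NIR",
    "NDVI",
    "GNDVI",
    "NDWI",
    "entropy",
    "contrast",
    "binary_txt",
]

NODATA_MASK = 255  # nodata value in uint8 canopy masks


@dataclass(frozen=True)
class RegionThresholds:
    """Per-region cutoffs for the binary texture layer."""

    ndvi_min: float
    entropy_min: float
    region_id: str = "default"

    def __post_init__(self):
        if not -1.0 <= self.ndvi_min <= 1.0:
            raise ValueError("ndvi_min must be in [-1, 1]")
        if self.entropy_min < 0:
            raise ValueError("entropy_min must be >= 0")


@dataclass
class FeatureStack:
    """Ten co-registered feature bands at imagery resolution."""

    raster: Raster

    def __post_init__(self):
        if self.raster.n_bands != len(FEATURE_BANDS):
            raise ValueError(f"feature stack must have exactly {len(FEATURE_BANDS)} bands")
        if self.raster.band_names != FEATURE_BANDS:
            raise ValueError(f"band schema must be {FEATURE_BANDS}")

    def band(self, name: str) -> np.ndarray:
        return self.raster.band(name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass
class AccuracyReport:
    confusion: np.ndarray  # 2x2 counts, rows = truth (not-tree, tree), cols = predicted
    overall: float
    users_tree: float
    producers_tree: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "overall": self.overall,
            "users_tree": self.users_tree,
            "producers_tree": self.producers_tree,
            "kappa": self.kappa,
        }


def _ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError(f"band shapes differ: {a.shape} vs {b.shape}")
    denom = a.astype(float) + b.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a.astype(float) - b.astype(float)) / denom
    out[denom == 0] = np.nan  # zero-denominator pixels are nodata
    return out


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized Difference Vegetation Index (NIR - R) / (NIR + R)."""
    return _ratio(nir, red)


def gndvi(nir: np.ndarray, green: np.ndarray) -> np.ndarray:
    """Green NDVI (NIR - G) / (NIR + G)."""
    return _ratio(nir, green)


def ndwi(green: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized Difference Water Index (G - NIR) / (G + NIR)."""
    return _ratio(green, nir)


def _quantize(grid: np.ndarray, levels: int) -> np.ndarray:
    """Quantize to int levels over the scene-wide finite range; nodata = -1."""
    finite = np.isfinite(grid)
    q = np.full(grid.shape, -1, dtype=np.int32)
    if not finite.any():
        return q
    lo, hi = grid[finite].min(), grid[finite].max()
    if hi <= lo:
        q[finite] = 0
        return q
    scaled = (grid[finite] - lo) / (hi - lo) * levels
    q[finite] = np.minimum(scaled.astype(np.int32), levels - 1)
    return q


def _pair_codes_window(q: np.ndarray, levels: int, direction: str) -> np.ndarray:
    """Symmetric co-occurrence codes for one direction within a window.

    Returns a 1-D array of codes i*levels+j for every ordered pair; pairs
    touching nodata are dropped.
    """
    if direction == "h":
        a, b = q[:, :-1], q[:, 1:]
    else:
        a, b = q[:-1, :], q[1:, :]
    valid = (a >= 0) & (b >= 0)
    a, b = a[valid], b[valid]
    return np.concatenate([a * levels + b, b * levels + a])


def _entropy_contrast_of_codes(codes: np.ndarray, levels: int) -> tuple[float, float]:
    if codes.size == 0:
        return np.nan, np.nan
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    i, j = np.divmod(np.unique(codes), levels)
    contrast = float((p * (i - j) ** 2).sum())
    return ent, contrast


def _window_textures_brute(q: np.ndarray, levels: int) -> tuple[float, float]:
    """Direction-averaged entropy/contrast of one window (reference path)."""
    ents, cons = [], []
    for d in ("h", "v"):
        codes = _pair_codes_window(q, levels, d)
        e, c = _entropy_contrast_of_codes(codes, levels)
        if np.isfinite(e):
            ents.append(e)
            cons.append(c)
    if not ents:
        return np.nan, np.nan
    return float(np.mean(ents)), float(np.mean(cons))


def _direction_maps(q: np.ndarray, levels: int, kernel: int, direction: str):
    """Vectorized per-pixel window entropy/contrast for interior anchors.

    For windows fully inside the grid: build the pair-code image for the
    direction, gather the codes of every window with sliding_window_view,
    and evaluate entropy via counts of equal codes within each row
    (entropy = -mean over valid elements of ln(c_e / m)).
    """
    h, w = q.shape
    if direction == "h":
        codes_f = np.where((q[:, :-1] >= 0) & (q[:, 1:] >= 0), q[:, :-1] * levels + q[:, 1:], -1)
        codes_r = np.where(codes_f >= 0, q[:, 1:] * levels + q[:, :-1], -1)
        win_shape = (kernel, kernel - 1)
    else:
        codes_f = np.where((q[:-1, :] >= 0) & (q[1:, :] >= 0), q[:-1, :] * levels + q[1:, :], -1)
        codes_r = np.where(codes_f >= 0, q[1:, :] * levels + q[:-1, :], -1)
        win_shape = (kernel - 1, kernel)

    from numpy.lib.stride_tricks import sliding_window_view

    wf = sliding_window_view(codes_f, win_shape).reshape(
        codes_f.shape[0] - win_shape[0] + 1, codes_f.shape[1] - win_shape[1] + 1, -1
    )
    wr = sliding_window_view(codes_r, win_shape).reshape(wf.shape)
    codes = np.concatenate([wf, wr], axis=-1)  # (H', W', m) symmetric code multiset
    hh, ww, m = codes.shape
    flat = codes.reshape(-1, m)
    ent = np.full(flat.shape[0], np.nan)
    con = np.full(flat.shape[0], np.nan)
    chunk = max(1, 2_000_000 // (m * m))
    for s in range(0, flat.shape[0], chunk):
        blk = flat[s : s + chunk]
        valid = blk >= 0
        eq = (blk[:, :, None] == blk[:, None, :]) & valid[:, :, None] & valid[:, None, :]
        counts = eq.sum(axis=2)
        mval = valid.sum(axis=1)
        ok = mval > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(valid, np.log(counts / mval[:, None]), 0.0)
        e = -logs.sum(axis=1) / np.maximum(mval, 1)
        i, j = np.divmod(np.where(valid, blk, 0), levels)
        c = np.where(valid, (i - j) ** 2, 0).sum(axis=1) / np.maximum(mval, 1)
        ent[s : s + chunk] = np.where(ok, e, np.nan)
        con[s : s + chunk] = np.where(ok, c, np.nan)
    return ent.reshape(hh, ww), con.reshape(hh, ww)


def glcm_textures(
    ndvi_grid: np.ndarray, kernel: int = 4, levels: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel GLCM entropy and contrast of quantized NDVI.

    Each pixel's window is the ``kernel`` x ``kernel`` neighborhood whose
    top-left corner sits ``kernel//2 - 1`` pixels up-left of the pixel;
    windows are clipped at the grid edge (available pixels only).
    """
    h, w = ndvi_grid.shape
    if kernel > min(h, w):
        raise ValueError(f"kernel {kernel} larger than grid {ndvi_grid.shape}")
    q = _quantize(ndvi_grid, levels)
    off = kernel // 2 - 1  # anchor offset of pixel inside its window

    ent_dirs, con_dirs = [], []
    for d in ("h", "v"):
        e_int, c_int = _direction_maps(q, levels, kernel, d)
        ent = np.full((h, w), np.nan)
        con = np.full((h, w), np.nan)
        # interior anchors: window top-left = (i - off, j - off)
        i0, j0 = off, off
        ent[i0 : i0 + e_int.shape[0], j0 : j0 + e_int.shape[1]] = e_int
        con[i0 : i0 + c_int.shape[0], j0 : j0 + c_int.shape[1]] = c_int
        ent_dirs.append(ent)
        con_dirs.append(con)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)  # all-nodata pixels
        entropy = np.nanmean(np.stack(ent_dirs), axis=0)
        contrast = np.nanmean(np.stack(con_dirs), axis=0)

    # borders: clipped windows, brute force (few pixels)
    border = np.zeros((h, w), dtype=bool)
    border[: off + 1, :] = True
    border[h - (kernel - off) + 1 :, :] = True
    border[:, : off + 1] = True
    border[:, w - (kernel - off) + 1 :] = True
    for i, j in zip(*np.nonzero(border)):
        r0, r1 = max(0, i - off), min(h, i - off + kernel)
        c0, c1 = max(0, j - off), min(w, j - off + kernel)
        e, c = _window_textures_brute(q[r0:r1, c0:c1], levels)
        entropy[i, j] = e
        contrast[i, j] = c
    return entropy, contrast


def glcm_entropy(ndvi_grid: np.ndarray, kernel: int = 4, levels: int = 32) -> np.ndarray:
    """GLCM entropy band (see :func:`glcm_textures`)."""
    return glcm_textures(ndvi_grid, kernel=kernel, levels=levels)[0]


def binary_texture_layer(
    entropy: np.ndarray, ndvi_grid: np.ndarray, thresholds: RegionThresholds
) -> np.ndarray:
    """1 where entropy > entropy_min AND NDVI > ndvi_min; nodata counts as 0."""
    if entropy.shape != ndvi_grid.shape:
        raise ValueError("grids must be co-registered")
    with np.errstate(invalid="ignore"):
        out = (entropy > thresholds.entropy_min) & (ndvi_grid > thresholds.ndvi_min)
    return out.astype(np.uint8)


def choose_thresholds(
    points: pd.DataFrame,
    stack: "FeatureStack | None" = None,
    *,
    entropy_at_points: np.ndarray | None = None,
    ndvi_at_points: np.ndarray | None = None,
    region_id: str = "default",
    n_grid: int = 25,
) -> RegionThresholds:
    """Grid-search (ndvi_min, entropy_min) maximizing balanced accuracy.

    The target is to flag forested training sites (label 1) while leaving
    grassy sites (green but smooth) at 0.  Feature values are sampled from
    ``stack`` at the points, or passed directly as arrays.  Ties break
    toward the higher threshold pair, ndvi_min first.
    """
    if stack is not None:
        feats = _features_at_points(stack, points)
        entropy_at_points = feats[:, FEATURE_BANDS.index("entropy")]
        ndvi_at_points = feats[:, FEATURE_BANDS.index("NDVI")]
    labels = points["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    ndvi_cands = np.quantile(ndvi_at_points[np.isfinite(ndvi_at_points)], np.linspace(0, 1, n_grid))
    ent_cands = np.quantile(
        entropy_at_points[np.isfinite(entropy_at_points)], np.linspace(0, 1, n_grid)
    )
    best = None
    for nv in ndvi_cands:
        for ev in ent_cands:
            pred = (entropy_at_points > ev) & (ndvi_at_points > nv)
            tpr = pred[labels == 1].mean()
            tnr = (~pred[labels == 0]).mean()
            bacc = 0.5 * (tpr + tnr)
            key = (bacc, nv, ev)  # tie-break toward higher thresholds
            if best is None or key > best[0]:
                best = (key, RegionThresholds(float(nv), float(max(ev, 0.0)), region_id))
    return best[1]


def build_feature_stack(
    imagery: Raster,
    thresholds: RegionThresholds | None = None,
    kernel: int = 4,
    levels: int = 32,
) -> FeatureStack:
    """Derive the ten-band stack from a 4-band (B, G, R, NIR) image.

    If no thresholds are given, the binary layer uses NDVI > 0.3 and
    entropy > the scene median entropy -- a serviceable default that
    :func:`choose_thresholds` refines per region.
    """
    b, g, r, nir = (imagery.band(n) for n in ["B", "G", "R", "NIR"])
    nd = ndvi(nir, r)
    gn = gndvi(nir, g)
    nw = ndwi(g, nir)
    ent, con = glcm_textures(nd, kernel=kernel, levels=levels)
    if thresholds is None:
        thresholds = RegionThresholds(0.3, float(np.nanmedian(ent)))
    btxt = binary_texture_layer(ent, nd, thresholds)
    data = np.stack(
        [b, g, r, nir, nd, gn, nw, ent, con, btxt.astype(np.float32)]
    ).astype(np.float32)
    return FeatureStack(
        Raster(
            data=data,
            res_m=imagery.res_m,
            origin=imagery.origin,
            band_names=list(FEATURE_BANDS),
            nodata=None,
        )
    )


def apply_thresholds(stack: FeatureStack, thresholds: RegionThresholds) -> FeatureStack:
    """Recompute the binary texture band under new region thresholds."""
    btxt = binary_texture_layer(stack.band("entropy"), stack.band("NDVI"), thresholds)
    data = stack.raster.data.copy()
    data[FEATURE_BANDS.index("binary_txt")] = btxt
    return FeatureStack(
        Raster(
            data=data,
            res_m=stack.raster.res_m,
            origin=stack.raster.origin,
            band_names=list(FEATURE_BANDS),
            nodata=stack.raster.nodata,
        )
    )


def accuracy_from_confusion(confusion: np.ndarray) -> AccuracyReport:
    """Overall, user's/producer's accuracy (tree class) and Cohen's kappa.

    Rows are truth (not-tree, tree), columns predicted.  kappa =
    (po - pe) / (1 - pe) with pe from the marginals.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / n**2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    users = cm[1, 1] / cm[:, 1].sum() if cm[:, 1].sum() else np.nan
    producers = cm[1, 1] / cm[1, :].sum() if cm[1, :].sum() else np.nan
    return AccuracyReport(
        confusion=cm.astype(int),
        overall=float(po),
        users_tree=float(users),
        producers_tree=float(producers),
        kappa=float(kappa),
    )


def _features_at_points(stack: FeatureStack, points: pd.DataFrame) -> np.ndarray:
    res = stack.raster.res_m
    ox, oy = stack.raster.origin
    h, w = stack.shape
    jj = np.floor((points["x"].to_numpy() - ox) / res).astype(int)
    ii = np.floor((points["y"].to_numpy() - oy) / res).astype(int)
    if (ii < 0).any() or (ii >= h).any() or (jj < 0).any() or (jj >= w).any():
        raise ValueError("control point outside imagery extent")
    return stack.raster.data[:, ii, jj].T  # (n_points, 10)


def train_classifier(
    stack: FeatureStack,
    points: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[RandomForestClassifier, AccuracyReport]:
    """Random forest over the ten feature values at labeled points.

    The accuracy report comes from out-of-bag predictions, so it is held out
    from the trees that vote on each point.
    """
    X = _features_at_points(stack, points)
    y = points["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need both tree and not-tree labels")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate features: all constant")
    X = np.nan_to_num(X, nan=0.0)
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, oob_score=True, n_jobs=1
    )
    model.fit(X, y)
    oob_pred = np.argmax(model.oob_decision_function_, axis=1)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, oob_pred):
        cm[t, p] += 1
    return model, accuracy_from_confusion(cm)


def classify(stack: FeatureStack, model: RandomForestClassifier) -> np.ndarray:
    """Predicted canopy mask: uint8 {0, 1}, nodata pixels = 255."""
    if getattr(model, "n_features_in_", len(FEATURE_BANDS)) != len(FEATURE_BANDS):
        raise ValueError("model feature schema does not match the ten-band stack")
    h, w = stack.shape
    X = stack.raster.data.reshape(len(FEATURE_BANDS), -1).T
    bad = ~np.isfinite(X).all(axis=1)
    Xf = np.nan_to_num(X, nan=0.0)
    pred = model.predict(Xf).astype(np.uint8)
    pred[bad] = NODATA_MASK
    return pred.reshape(h, w)
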