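# Methods

This note documents the models, conventions and parameter choices behind
`treequity`, in the spirit of a statistical-software methods appendix: what
each stage assumes, which knobs matter, and what the synthetic validation
does and does not demonstrate.

## Canopy classification

**Feature stack.** Ten co-registered 2 m bands: B, G, R, NIR reflectance;
NDVI, GNDVI, NDWI band ratios (nodata where the denominator is zero); GLCM
entropy and GLCM contrast of quantized NDVI; and a binary layer that is 1
where entropy and NDVI both exceed region-specific thresholds. Two texture
bands are included because the stack is defined as ten bands while only
three ratio indices are standard; contrast comes for free from the same
co-occurrence pass and adds an independent texture axis.

**GLCM parameterization.** Published descriptions of windowed texture
rarely pin the details, so ours are explicit and configurable:

- NDVI is quantized to L = 32 gray levels over the *scene-wide* finite
  range, not per window, so entropy is comparable across the scene.
- Co-occurrence pairs at offset 1 in the horizontal and vertical
  directions, accumulated symmetrically (each pair in both orders); the two
  directions are computed separately and their entropies averaged —
  standard texture practice.
- Window: 4×4 pixels, anchored so the target pixel sits at position (1,1);
  edge windows are clipped to the available pixels. Pairs touching nodata
  are dropped.
- Entropy = −Σ p ln p over co-occurrence cells (natural log; a constant
  window gives 0, a two-level checkerboard gives ln 2, and ln L² bounds the
  maximum). Contrast = Σ p (i−j)².

The production path vectorizes interior windows (pair-code gathering via
sliding windows, entropy from within-row equality counts) and brute-forces
the border; tests verify exact agreement with an independent enumeration
and with scikit-image's co-occurrence matrix on single windows.

**Thresholds and classifier.** `choose_thresholds` grid-searches 25×25
quantile-spaced candidate pairs maximizing balanced accuracy of the binary
layer against training labels, breaking ties toward higher thresholds
(prefer missing marginal trees over flagging grass). The classifier is a
100-tree random forest (fixed seed, one job) over the ten feature values at
each control point; accuracy is reported from out-of-bag votes as a 2×2
confusion matrix with overall, user's and producer's accuracy for the tree
class, and Cohen's kappa = (p_o − p_e)/(1 − p_e).

## Thermal compositing

Scenes are Kelvin grids with a QA integer band; a pixel is dropped when QA
bit 5 (cloud) or bit 2 (cloud shadow) is set, or when the static water mask
covers it. The composite is the per-pixel median over scenes dated inside
Jun 21 – Sep 22 (both endpoints inclusive), converted to °C; the even-count
median is the mean of the two middle values; pixels with zero unmasked
observations are NaN. Block temperature is the *mean* of 30 m pixel centers
inside the block polygon — the zonal statistic at block level is a genuine
free choice, and mean is used (flagged here) rather than median.

## Census integration

- Blocks are retained when fully inside the urbanized-area boundary
  buffered out 100 m and when population > 0.
- Income attaches at block-group level by block-centroid containment; when
  SE/estimate > 0.34 (strict inequality; CV exactly 0.34 keeps the
  block-group value) the parent tract's estimate substitutes. The CV is
  SE-based; a margin-of-error-based variant would differ only by a constant
  factor.
- Block canopy fraction = (tree pixels with centers inside) × pixel area /
  polygon area, clipped to [0, 1]. Pixel-center containment is the single
  polygon/raster convention across the package.
- Density = population / (land area in km²).

## Stratification

Income quartiles are formed within each urbanized area by block count
(labels 1–4), with ties resolved by stable ordering on block_id. Density
classes are half-open: [0, 2000), [2000, 4000), [4000, 8000), [8000, ∞)
people/km². The population-weighted median is the smallest value whose
cumulative block population reaches half the total — the lower-value rule,
no interpolation; with unit weights it reduces to the lower-middle
convention. Study-wide tables pool blocks across UAs by default; a
`per_ua_mean` mode averaging per-UA cell medians is provided because both
readings of "averaging across urbanized areas" are defensible.

## Among-UA regression

Responses: arcsine-transformed (asin √p) population-weighted median cover,
and the Q4 − Q1 gap as a *difference of arcsine medians* (it can be
negative, so it needs no further transform). The arcsine form is pinned by
the back-transform identities: from a 27% base, +0.1/+0.2/+0.3 in
transformed space are +9.3/+19.1/+29.1 cover points. Candidate predictors:
median and IQR of per-capita income, log median density, IQR density, and
biome as a dummy group added or dropped as one unit. Forward selection
minimizes OLS AIC with deterministic (lexicographic) tie-breaks. The final
model is a spatial-lag SAR fit by maximum likelihood with the concentrated
likelihood in ρ: β(ρ) and σ²(ρ) are closed-form, ln|I − ρW| = Σ ln(1 −
ρλᵢ) over the eigenvalues of W, and ρ is searched on (−1, 1) (bounded
scalar optimization). Weights are binary 500 km distance-band neighbors
over UA centroids, row-standardized; W = 0 reduces the fit exactly to least
squares. Coefficient standard errors use the conditional-on-ρ̂ OLS
covariance σ²(X'X)⁻¹ — adequate for the simulation scales here, slightly
anti-conservative in general. Moran's I with permutation p-values (999
permutations, one-sided toward the observed deviation from E[I] = −1/(n−1))
diagnoses residual autocorrelation.

A caution on selection: under a null response, forward selection still
admits noise predictors in a substantial minority of runs, and their
post-selection p-values are not uniform. The tests therefore check
calibration on a *fixed* coefficient in the unselected model and
near-emptiness of null selections, not "no significant predictor ever".

## Within-UA block bootstrap

Arcsine cover is regressed on categorical predictors — density class,
income quartile, within-UA BUI (built-up intensity) quartile, and
majority-non-Hispanic-white (strictly > 50%) — with each group's lowest
category as baseline. Blocks are unweighted. Columns that are empty or
exactly aliased in a UA's design (small UAs can have, e.g., no top-BUI
blocks) are dropped via pivoted QR before resampling.

Blocks are binned into 2 km tiles by centroid (half-open intervals anchored
at the bounding-box minimum). Each of the (default 1000) replicates draws
tiles with replacement up to the original tile count, pools their blocks,
and refits by least squares; rank-deficient replicates are redrawn and
counted. Two significance readings are reported:

- `significant`: ≥ 95% of draws share the point estimate's sign. Because
  the direction is taken from the data, this is a two-sided test with
  nominal size 10%.
- `one_tailed_significant(name, alternative)`: ≥ 95% of draws on the
  *hypothesized* side (income positive; density and BUI negative), the 5%
  one-tailed test matching directional hypotheses stated in advance. The
  calibration experiments in the test suite use this rule; measured type-I
  under a null income effect is 8.5% across 200 simulated UAs (200
  replicates each), and power against a strong income effect
  (beta_income_canopy = 0.24) is 100%.

Calibration depends on tile count: with ~100 tiles the bootstrap sd is a
mildly noisy, slightly downward-biased estimate of the sampling sd, and the
one-tailed rule lands near its nominal size. In small cities (< ~25 tiles)
the tile resample is too lumpy for calibrated inference — a property of the
method, not of this implementation.

The method-of-moments empirical variogram (γ(h) = mean of ½(zᵢ−zⱼ)² per
distance bin) supports residual-autocorrelation checks; identical
coordinates land in the first bin.

## Disparity ledger

Per (UA, density class): disparity = max(0, high-income median cover % −
low-income median cover %), by default floored at zero before aggregation
because a canopy surplus in one city cannot offset a deficit in another
(an unfloored mode exists). Needed canopy = disparity/100 × land area of
the low-income blocks in that cell. Conversions: 19.6 m² canopy per tree
(from a national stock estimate: 5.5 × 10⁹ urban trees over 67.6 M acres at
39.3% mean cover — the derivation gives 19.55 m², the conventional printed
factor 19.6 is the default constant); $283 per planted stem; compensatory
(appraisal) value per stem of $904.4 (median), $653.8 (low), $1,812.1
(high), back-computed from published national totals because primary
per-stem figures are not printed alongside them. Tree counts round to the
nearest integer; per-person value rounds to the nearest dollar over the
low-income population. `verify-table2` replays this arithmetic chain
against the published national reference table, tolerating exactly the
printed precision (areas to 1 km², money to $0.1 B).

## Synthetic cities: what they emulate, and what they do not

One seed drives everything through `numpy.random.SeedSequence` spawns (one
child per sub-generator), so outputs are byte-reproducible and regenerating
one component does not perturb the others.

**Geometry.** A square extent tiled by rectangular blocks (near-square
grid factorization), nested into block groups and tracts; areas are planar
m², no geodesy. Default city: 2.4 km, 576 blocks of 100 m, 36 block
groups, 9 tracts, 25,000 residents.

**Population and density.** A radial exponential density gradient
(e-folding scale 600 m by default — "densest in the center") times a
lognormal texture, integerized by largest-remainder rounding so block
populations sum exactly to the configured total. Defaults span all four
density classes.

**Income.** A Gaussian-field rank surface over block groups at the
configured correlation range, mixed with an iid nugget (default half the
variance) that stands in for ACS sampling error, mapped through the
lognormal quantile function (μ = 10.3, σ = 0.5 → median ≈ $30 k per
capita). Standard errors give a configurable minority (10%) of block groups
CV > 0.34 to exercise the tract fallback. An optional center gradient
couples income to distance from center; it defaults off so that the
income–canopy association is governed by `beta_income_canopy` alone.

**Canopy.** Per-block target fraction = base (0.45) + 0.24 × (income
percentile − 0.5) − 0.09 × density class + a spatially correlated
disturbance (sd 0.06, range 1 km), clipped to [0.02, 0.95]. The default
slope mirrors a cover-vs-income-percentile gradient of about 1.2 points per
5 percentiles; the density decay of ~9 points per class and the base mirror
published stratified medians. Pixels realize the target by thresholding a
24 m "crown" field per block, giving clumped canopy whose per-block
fraction matches the target to pixel rounding; truth tables are computed
from the realized mask, so oracle checks are exact.

**Other classes.** Water blobs (3% of area, range 400 m) override canopy;
remaining pixels split into impervious (15/35/55/75% by density class),
soil (8%) and grass along a spatially coherent uniformized field.

**Reflectance.** Class-mean B/G/R/NIR with small Gaussian noise; trees and
grass share high NIR and NDVI (≈ 0.7–0.75) but trees carry strong R/NIR
speckle (sd 0.03/0.12) emulating sunlit-crown/shadow mottling — this is
what gives trees high GLCM entropy and makes texture, not greenness, the
discriminating feature. Water has G > NIR (NDWI > 0); impervious has
NIR ≈ R (NDVI ≈ 0.02).

**Temperature.** 30 m truth = 30 °C baseline + temp_per_canopy × cell
canopy fraction (default −10 °C per unit cover, consistent in magnitude
with a ~1.5 °C gap accompanying a ~15-point cover gap) + a smooth 500 m
disturbance (sd 0.3). Scenes add a per-scene offset (sd 2 K) and pixel
noise (sd 0.5 K); cloud blobs set QA bit 5 on ~80% of the masked budget and
their shifted shadows bit 2 on the rest; dates are uniform over the summer
window of 2000–2019.

**Race, age, BUI.** Proportion non-Hispanic white is a two-component Beta
mixture (Beta(8,2) vs Beta(2,8), weights 0.6/0.4) — the bimodal
"predominantly white or predominantly non-white" pattern — with the
component probability mildly coupled to income percentile (0.3). Median age
is normal around 38 with a weak income tilt. BUI is a saturating function
of density plus lognormal noise.

**Not emulated:** street networks and realistic urban morphology, mixed
land-use parcels, sensor georegistration error, atmospheric effects,
emissivity, temporal land-cover change, income–density joint distributions
beyond the optional center gradient, and real biome geography (biomes are
labels that shift baseline canopy in multi-city studies). Passing tests
demonstrate that the pipeline's estimators recover known structure under
these idealized conditions; they do not certify accuracy on real imagery,
where class separability and label quality are far worse.

## Problem sizes used in the test battery

Chosen as desk-scale analogs: the default 1200×1200-pixel city for
block-level canopy validation (R ≥ 0.95, median |error| ≤ 6 points);
200 simulated 19.2 km UAs × 200 bootstrap replicates for type-I
calibration and 50 for power; 100 replicate fits at n = 100 UAs for ρ
recovery (±0.15 for ρ ∈ {0, 0.5}); 1000 random instances for the
weighted-median oracle. The full suite runs in about two minutes on one
CPU.

## Data dictionary (block table)

| column | meaning |
| --- | --- |
| `block_id`, `bg_id`, `tract_id`, `ua_id` | nested geography identifiers |
| `geometry` | block polygon, planar meters (WKT in CSV) |
| `cx`, `cy` | block centroid coordinates, m |
| `land_area_m2` | land area (Aland analog) |
| `population` | residents (TotPop analog) |
| `n_nonhisp_white` | non-Hispanic white residents (NoHiWhite analog) |
| `median_age` | years (MedAge analog) |
| `income_per_capita` | USD, block-group or tract estimate (IncPr analog) |
| `income_source` | `block_group` or `tract` (CV fallback) |
| `bui` | built-up intensity, floor-area ratio |
| `canopy_fraction` | tree-cover fraction in [0, 1] |
| `temperature_c` | composite summer surface temperature, °C |
| `density` | people per km² |

Fractions are stored in [0, 1]; percentages appear only in rendered
tables.

## Known limitations

- No geodesy: everything is planar; real analyses need projected CRS
  handling and area corrections.
- Raster I/O is plain TIFF plus a JSON georeferencing sidecar, and vector
  tables are CSV with WKT geometry.
- The lag-model standard errors are conditional on ρ̂; a full information
  matrix would widen them slightly.
- The `significant` sign-agreement flag is a 10%-size two-sided test by
  construction; use the one-tailed reading for directional hypotheses.
- Regional ("biome") classifier groups are arbitrary partitions with
  per-group thresholds/models, not real ecoregions.
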