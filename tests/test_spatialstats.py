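"""Transforms, Moran's I, the lag model, forward selection, the bootstrap."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from treequity import spatialstats as sp
from treequity import strata, synth


class TestArcsine:
    def test_boundaries(self):
        assert sp.arcsine(0.0) == 0.0
        assert sp.arcsine(1.0) == pytest.approx(np.pi / 2)

    @pytest.mark.parametrize("inc,expected", [(0.1, 9.3), (0.2, 19.1), (0.3, 29.1)])
    def test_back_transform_increments_from_27pct(self, inc, expected):
        t = sp.arcsine(0.27)
        gain = 100 * (sp.arcsine_inverse(t + inc) - 0.27)
        assert round(float(gain), 1) == expected

    @given(st.floats(0.0, 1.0))
    def test_roundtrip_exact(self, p):
        assert sp.arcsine_inverse(sp.arcsine(p)) == pytest.approx(p, abs=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            sp.arcsine(1.2)
        with pytest.raises(ValueError):
            sp.arcsine_inverse(2.0)


@pytest.fixture(scope="module")
def weights_100():
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 1000, (100, 2))
    return coords, sp.distance_band_weights(coords, 200.0)


class TestWeights:
    def test_rows_standardized(self, weights_100):
        _, w = weights_100
        sums = w.matrix.sum(axis=1)
        assert np.allclose(sums[w.n_neighbors > 0], 1.0)
        assert np.allclose(np.diag(w.matrix), 0.0)


class TestMoransI:
    def test_iid_residuals_near_null_mean(self, weights_100):
        _, w = weights_100
        n = 100
        vals = [
            sp.morans_i(np.random.default_rng(s).normal(size=n), w, permutations=99)[0]
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_smooth_surface_detected(self, weights_100):
        coords, w = weights_100
        z = coords[:, 0] / 1000 + np.sin(coords[:, 1] / 300)
        i, p = sp.morans_i(z, w, seed=1)
        assert i > 0 and p < 0.05

    def test_scale_invariance(self, weights_100):
        _, w = weights_100
        z = np.random.default_rng(9).normal(size=100)
        i1, p1 = sp.morans_i(z, w, seed=3)
        i2, p2 = sp.morans_i(1000 * z, w, seed=3)
        assert i1 == pytest.approx(i2) and p1 == p2

    def test_no_neighbors_raises(self):
        w = sp.SpatialWeights(np.zeros((5, 5)), 1.0, np.zeros(5, int))
        with pytest.raises(ValueError, match="neighbors"):
            sp.morans_i(np.arange(5.0), w)


def simulate_sar(rho, W, seed, n=100):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    xb = np.column_stack([np.ones(n), X]) @ np.array([1.0, 2.0, -1.5])
    y = np.linalg.solve(np.eye(n) - rho * W, xb + rng.normal(size=n))
    return y, X


class TestSpatialLag:
    @pytest.mark.parametrize("rho_true", [0.0, 0.5])
    def test_rho_recovery(self, weights_100, rho_true):
        _, w = weights_100
        rhos = [
            sp.fit_spatial_lag(*simulate_sar(rho_true, w.matrix, 500 + k), w).rho
            for k in range(100)
        ]
        assert np.mean(rhos) == pytest.approx(rho_true, abs=0.15)

    def test_beta_matches_ols_when_rho_zero(self, weights_100):
        _, w = weights_100
        y, X = simulate_sar(0.0, w.matrix, 77)
        fit = sp.fit_spatial_lag(y, X, w)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.betas, ols.params, atol=0.3)

    def test_zero_weights_reduce_to_least_squares(self, weights_100):
        _, w = weights_100
        y, X = simulate_sar(0.0, w.matrix, 5)
        w0 = sp.SpatialWeights(np.zeros((100, 100)), 1.0, np.zeros(100, int))
        fit = sp.fit_spatial_lag(y, X, w0)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.rho == 0.0
        assert np.allclose(fit.betas, ols.params, atol=1e-8)
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)

    def test_loglik_at_rho_zero_equals_ols_loglik(self, weights_100):
        """Analytic agreement: concentrated lag likelihood at rho = 0 is the
        least-squares log-likelihood (the Jacobian term vanishes)."""
        _, w = weights_100
        y, X = simulate_sar(0.3, w.matrix, 8)
        Xc = np.column_stack([np.ones(len(y)), X])
        ols = sm.OLS(y, Xc).fit()
        n = len(y)
        sse = float(ols.resid @ ols.resid)
        ll0 = -n / 2 * (np.log(2 * np.pi) + 1 + np.log(sse / n))
        assert ll0 == pytest.approx(ols.llf, abs=1e-9)

    def test_aic_identity(self, weights_100):
        _, w = weights_100
        y, X = simulate_sar(0.2, w.matrix, 12)
        fit = sp.fit_spatial_lag(y, X, w)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (len(fit.betas) + 2))
        assert abs(fit.rho) < 1

    def test_singular_design_raises(self, weights_100):
        _, w = weights_100
        y, X = simulate_sar(0.0, w.matrix, 13)
        Xs = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(ValueError, match="singular"):
            sp.fit_spatial_lag(y, Xs, w)


class TestForwardAIC:
    def test_true_predictor_selected_first(self):
        rng = np.random.default_rng(1)
        n = 100
        cands = {f"c{i}": rng.normal(size=n) for i in range(5)}
        y = 2.0 * cands["c3"] + rng.normal(0, 0.5, n)
        selected = sp.forward_aic(y, cands)
        assert selected[0] == "c3"

    def test_pure_noise_selects_near_empty(self):
        rng = np.random.default_rng(9)
        sizes = []
        for _ in range(100):
            y = rng.normal(size=60)
            cands = {f"c{i}": rng.normal(size=60) for i in range(5)}
            sizes.append(len(sp.forward_aic(y, cands)))
        sizes = np.array(sizes)
        assert (sizes <= 2).mean() >= 0.9
        assert sizes.mean() < 1.5

    def test_aic_tie_prefers_lexicographically_first(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.1, 50)
        cands = {"b_dup": x, "a_dup": x.copy()}
        assert sp.forward_aic(y, cands)[0] == "a_dup"

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            sp.forward_aic(np.zeros(10), {})


@pytest.fixture(scope="module")
def study():
    blocks, ua = synth.simulate_study(n_uas=30, seed=4)
    return strata.ua_level_table(blocks, ua)


class TestAmongUA:

    def test_biome_driving_canopy_is_selected_and_significant(self, study):
        res = sp.among_ua_regressions(study)
        r = res["median_cover"]
        assert "biome" in r["selected"]
        biome_p = [p for n, p in zip(r["fit"].names, r["fit"].pvalues) if n.startswith("biome")]
        assert min(biome_p) < 0.05

    def test_deterministic_given_inputs(self, study):
        r1 = sp.among_ua_regressions(study)
        r2 = sp.among_ua_regressions(study)
        assert r1["median_cover"]["fit"].rho == r2["median_cover"]["fit"].rho
        assert np.array_equal(r1["income_gap"]["fit"].betas, r2["income_gap"]["fit"].betas)

    def test_fixed_coefficient_calibrated_under_null(self, study):
        """Type-I calibration that survives selection effects: the
        median_income coefficient in the full (unselected) lag fit is
        significant at 5% in roughly 5% of null responses."""
        rng = np.random.default_rng(17)
        coords = study[["x_m", "y_m"]].to_numpy(float)
        w = sp.distance_band_weights(coords, 500_000.0)
        X = np.column_stack(
            [
                study["median_income"].to_numpy(float),
                np.log(study["median_density"].to_numpy(float)),
            ]
        )
        hits = 0
        runs = 60
        for _ in range(runs):
            y = rng.normal(size=len(study))
            fit = sp.fit_spatial_lag(y, X, w, names=["median_income", "log_density"])
            hits += fit.pvalues[fit.names.index("median_income")] < 0.05
        assert hits / runs <= 0.15

    def test_requires_twenty_uas(self, study):
        with pytest.raises(ValueError, match="20"):
            sp.among_ua_regressions(study.head(5))


def _sim_ua(beta, seed, extent=9600, nb=576, nbg=144, pop=400_000):
    cfg = synth.CityConfig(
        grid_extent_m=extent,
        n_blocks=nb,
        n_block_groups=nbg,
        n_tracts=min(16, nbg),
        total_population=pop,
        beta_income_canopy=beta,
        autocorr_range_m=500,
        center_density_scale_m=extent / 4,
        seed=seed,
    )
    return synth.simulate_block_table(cfg)


class TestBlockBootstrap:
    def test_single_rep_reproducible(self):
        bl = _sim_ua(0.24, 101)
        f1 = sp.block_bootstrap_fit(bl, reps=1, seed=5)
        f2 = sp.block_bootstrap_fit(bl, reps=1, seed=5)
        assert np.array_equal(f1.draws, f2.draws)
        assert np.array_equal(f1.estimates, f2.estimates)

    def test_block_order_invariance(self):
        bl = _sim_ua(0.24, 102)
        f1 = sp.block_bootstrap_fit(bl, reps=50, seed=7)
        f2 = sp.block_bootstrap_fit(
            bl.sample(frac=1, random_state=3).reset_index(drop=True), reps=50, seed=7
        )
        assert np.allclose(f1.estimates, f2.estimates, atol=1e-10)
        assert np.array_equal(f1.significant, f2.significant)

    def test_strong_income_effect_detected(self):
        bl = _sim_ua(0.24, 103)
        fit = sp.block_bootstrap_fit(bl, reps=200, seed=1)
        assert fit.one_tailed_significant("income_q_4", "greater")
        assert fit.significant[fit.names.index("income_q_4")]

    def test_density_effect_negative_and_detected(self):
        bl = _sim_ua(0.24, 104)
        fit = sp.block_bootstrap_fit(bl, reps=200, seed=2)
        k = fit.names.index("density_High")
        assert fit.estimates[k] < 0
        assert fit.one_tailed_significant("density_High", "less")

    def test_significance_flag_matches_sign_agreement_invariant(self):
        bl = _sim_ua(0.1, 105)
        fit = sp.block_bootstrap_fit(bl, reps=100, seed=3)
        expected = (fit.sign_agreement >= 0.95) & (fit.estimates != 0)
        assert np.array_equal(fit.significant, expected)
        assert fit.draws.shape == (100, len(fit.names))

    def test_too_few_tiles_raises(self):
        bl = _sim_ua(0.2, 106, extent=1200, nb=36, nbg=9, pop=20_000)
        with pytest.raises(ValueError, match="tiles"):
            sp.block_bootstrap_fit(bl, tile_m=5000.0, reps=10, seed=0)


class TestVariogram:
    def test_iid_residuals_flat(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 5000, (300, 2))
        vals = rng.normal(size=300)
        vg = sp.empirical_variogram(vals, coords, max_lag_m=3000)
        rho = spearmanr(vg["lag_mid_m"], vg["semivariance"]).statistic
        assert abs(rho) < 0.5

    def test_known_range_shows_rise_then_sill(self):
        rng = np.random.default_rng(6)
        n = 40
        xs = np.linspace(0, 3900, n)
        gx, gy = np.meshgrid(xs, xs)
        field = synth.gaussian_field((n, n), 1000.0, 100.0, rng)
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        vals = field.ravel()
        sel = rng.choice(len(vals), 500, replace=False)
        vg = sp.empirical_variogram(vals[sel], coords[sel], max_lag_m=3000, n_bins=10)
        short = vg[vg["lag_mid_m"] < 500]["semivariance"].mean()
        sill = vg[vg["lag_mid_m"] > 1500]["semivariance"].mean()
        assert short < 0.5 * sill

    def test_duplicate_coordinates_fall_in_first_bin(self):
        coords = np.zeros((40, 2))
        coords[20:, 0] = 1000.0
        vals = np.r_[np.zeros(20), np.ones(20)]
        vg = sp.empirical_variogram(vals, coords, max_lag_m=2000, n_bins=4)
        assert vg.iloc[0]["semivariance"] == 0.0  # identical points, zero lag

    def test_minimum_points_enforced(self):
        with pytest.raises(ValueError, match="30"):
            sp.empirical_variogram(np.zeros(5), np.zeros((5, 2)), 100.0)
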