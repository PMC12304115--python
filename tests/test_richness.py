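import numpy as np
import pytest
from scipy import stats

from fishdiv.richness import (
    RichnessModel,
    adjusted_r2_value,
    bootstrap_params,
    diagnostics,
    fit_mle,
    fit_region_split,
    likelihood_ratio_test,
    loocv,
    profile_ci,
    variance_components,
)
from fishdiv.synthetic import ModelTruth, generate_observations


@pytest.fixture(scope="module")
def noisefree(small_landscape, truth):
    obs, _ = generate_observations(small_landscape, truth, sigma=0.0, seed=21)
    model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                          fields=small_landscape.fields,
                          lulc=small_landscape.lulc,
                          areas=small_landscape.areas)
    return model


@pytest.fixture(scope="module")
def noisy(small_landscape, truth):
    obs, _ = generate_observations(small_landscape, truth, sigma=5.0, seed=22)
    return RichnessModel(B=obs["richness"], Q=obs["discharge"],
                         fields=small_landscape.fields,
                         lulc=small_landscape.lulc,
                         areas=small_landscape.areas)


class TestProfileFit:
    def test_noise_free_profile_peaks_at_true_r(self, noisefree, truth):
        # a grid containing the true r: the profile must be maximized there
        grid = np.unique(np.append(np.geomspace(1.0, 500.0, 60), truth.r))
        fit = noisefree.fit(r_grid=grid)
        assert fit.params.r == pytest.approx(truth.r, abs=1e-6)
        assert np.max(np.abs(fit.residuals)) <= 1e-8
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_translation_invariance(self, noisy):
        f0 = noisy.fit()
        f1 = noisy.fit(y=noisy.B + 7.0)
        assert f1.params.a == pytest.approx(f0.params.a + 7.0, abs=1e-6)
        assert f1.params.b == pytest.approx(f0.params.b, abs=1e-6)
        np.testing.assert_allclose(f1.params.V, f0.params.V, atol=1e-5)
        assert f1.params.r == pytest.approx(f0.params.r, abs=1e-6)

    def test_site_order_exchangeability(self, small_landscape, truth):
        obs, _ = generate_observations(small_landscape, truth, sigma=5.0,
                                       seed=23)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        fit = model.fit()
        perm = np.random.default_rng(0).permutation(model.M)
        fit_p = model.subset(perm).fit()
        assert fit_p.params.r == pytest.approx(fit.params.r, rel=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, rel=1e-9)
        np.testing.assert_allclose(fit_p.params.V, fit.params.V, rtol=1e-6)

    def test_fixed_r_mle_equals_closed_form_ols(self, noisy):
        """The profile step is exactly OLS on [1, lnQ, C(r)]."""
        r = 17.0
        X, _ = noisy.design(r)
        beta_np, *_ = np.linalg.lstsq(X, noisy.B, rcond=None)
        prof = noisy.profile_loglik_over_r(np.array([r]))
        rss = float(((noisy.B - X @ beta_np) ** 2).sum())
        expect_ll = -0.5 * noisy.M * (np.log(rss / noisy.M)
                                      + np.log(2 * np.pi) + 1)
        assert prof["loglik"].iloc[0] == pytest.approx(expect_ll, rel=1e-12)

    def test_invariant_to_area_rescaling(self, small_landscape, noisy):
        """Scaling all pixel areas by s and V by 1/s leaves the fit alone."""
        fit = noisy.fit()
        import copy
        scaled = copy.deepcopy(noisy.exposure)
        scaled._a = scaled._a * 3.0
        model2 = RichnessModel(B=noisy.B, Q=np.exp(noisy.lnQ),
                               exposure=scaled)
        fit2 = model2.fit()
        assert fit2.loglik == pytest.approx(fit.loglik, rel=1e-9)
        np.testing.assert_allclose(fit2.params.V * 3.0, fit.params.V,
                                   rtol=1e-6)


class TestLRT:
    def test_identical_models_give_p_one(self, noisy):
        fit = noisy.fit()
        assert likelihood_ratio_test(fit, fit, df=1) == 1.0

    def test_chi_square_reference_value(self):
        # statistic 3.841 on 1 df sits at the 5% point
        p = likelihood_ratio_test(3.841 / 2.0, 0.0, df=1)
        assert p == pytest.approx(0.0500, abs=0.0005)

    def test_p_monotone_in_statistic(self):
        stats_seq = [0.5, 1.0, 2.0, 4.0, 8.0]
        ps = [likelihood_ratio_test(s / 2, 0.0, df=1) for s in stats_seq]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_non_nested_rejected(self, noisy):
        fit = noisy.fit()
        with pytest.raises(ValueError):
            likelihood_ratio_test(fit.loglik - 5.0, fit.loglik, df=1)


class TestAdjustedR2:
    def test_perfect_fit(self, noisefree):
        assert noisefree.fit().adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only_is_zero(self):
        assert adjusted_r2_value(0.0, 30, 0) == 0.0

    def test_hand_computation_six_points(self):
        # R2 = 0.8, M = 6, p = 2: 1 - 0.2 * 5 / 3
        assert adjusted_r2_value(0.8, 6, 2) == pytest.approx(1 - 0.2 * 5 / 3)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            adjusted_r2_value(0.9, 5, 4)


class TestProfileCI:
    def test_mle_inside_its_own_interval(self, noisy):
        fit = noisy.fit()
        ci = profile_ci(noisy, fit, "r", level=0.90)
        assert ci["lo"] <= fit.params.r <= ci["hi"]

    def test_nesting_of_levels(self, noisy):
        fit = noisy.fit()
        ci50 = profile_ci(noisy, fit, "r", level=0.50)
        ci90 = profile_ci(noisy, fit, "r", level=0.90)
        assert ci90["lo"] <= ci50["lo"] <= ci50["hi"] <= ci90["hi"]

    def test_linear_parameter_matches_wald(self, truth):
        """At large M the profile interval for b converges to the ±1.645 SE
        normal-theory Wald interval, with the SE from the full delta-method
        Jacobian (linear columns plus the r-sensitivity direction)."""
        from fishdiv.synthetic import generate_landscape, generate_observations
        land = generate_landscape(n_sites=150, seed=77,
                                  min_spacing_pixels=4)
        obs, _ = generate_observations(land, truth, sigma=3.0, seed=78)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=land.fields, lulc=land.lulc,
                              areas=land.areas)
        fit = model.fit()
        ci = profile_ci(model, fit, "b", level=0.90)
        r_hat = fit.params.r
        X, names = model.design(r_hat)
        h = 1e-4 * r_hat
        V_act = fit.params.V[model.active_classes]
        dmu_dr = (model.exposure.matrix(r_hat + h)[:, model.active_classes]
                  - model.exposure.matrix(r_hat - h)[:, model.active_classes]
                  ) @ V_act / (2 * h)
        J = np.column_stack([X, dmu_dr])
        j = names.index("b")
        df = model.M - J.shape[1]
        sigma2 = fit.sigma2 * model.M / df
        se = np.sqrt(sigma2 * np.linalg.inv(J.T @ J)[j, j])
        half_wald = stats.t.ppf(0.95, df) * se
        half_prof = 0.5 * (ci["hi"] - ci["lo"])
        assert half_prof == pytest.approx(half_wald, rel=0.01)


class TestLOOCV:
    def test_noise_free_rmse_small(self, noisefree):
        rmse, table = loocv(noisefree, refine=False)
        assert 0.0 <= rmse <= 0.5
        assert not table["failed"].any()

    def test_matches_manual_fold_oracle(self, small_landscape, truth):
        obs, _ = generate_observations(small_landscape, truth, sigma=4.0,
                                       seed=31)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        rmse, table = loocv(model, refine=False)
        # independent oracle: explicit per-fold OLS over the same r grid
        r_grid = np.geomspace(model.r_bounds[0], model.r_bounds[1],
                              model.n_grid)
        preds = np.zeros(model.M)
        for i in range(model.M):
            keep = np.array([j for j in range(model.M) if j != i])
            best = None
            for r in r_grid:
                C = model.exposure.matrix(r)
                X = np.column_stack([np.ones(model.M), model.lnQ, C[
                    :, model.active_classes]])
                beta, *_ = np.linalg.lstsq(X[keep], model.B[keep], rcond=None)
                rss = float(((model.B[keep] - X[keep] @ beta) ** 2).sum())
                if best is None or rss < best[0]:
                    best = (rss, X[i] @ beta)
            preds[i] = best[1]
        oracle_rmse = float(np.sqrt(np.mean((model.B - preds) ** 2)))
        assert rmse == pytest.approx(oracle_rmse, rel=1e-9)
        np.testing.assert_allclose(table["predicted"], preds, rtol=1e-9)


class TestBootstrap:
    def test_noise_free_draws_degenerate(self, noisefree):
        draws = bootstrap_params(noisefree, n_boot=12, seed=5)
        for col in ["a", "b", "V1", "V3"]:
            iqr = draws[col].quantile(0.75) - draws[col].quantile(0.25)
            assert iqr == pytest.approx(0.0, abs=1e-6)

    def test_seeded_reproducibility(self, noisy):
        d1 = bootstrap_params(noisy, n_boot=8, seed=3, refine=False)
        d2 = bootstrap_params(noisy, n_boot=8, seed=3, refine=False)
        assert d1.equals(d2)


class TestVarianceComponents:
    def test_null_discharge_truth(self, small_landscape):
        theta = ModelTruth(r=19.0, a=20.0, b=0.0,
                           V=np.array([1.4, -0.2, -2.2, -4.9, -3.7]))
        obs, _ = generate_observations(small_landscape, theta, sigma=1.0,
                                       seed=41)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        vc = variance_components(model)
        assert vc["discharge_only"]["adj_r2"] < 0.3
        assert vc["full"]["r2"] >= max(vc["lulc_only"]["r2"],
                                       vc["discharge_only"]["r2"])

    def test_null_lulc_truth(self, small_landscape):
        theta = ModelTruth(r=19.0, a=20.0, b=3.0, V=np.zeros(5))
        obs, _ = generate_observations(small_landscape, theta, sigma=1.0,
                                       seed=42)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        vc = variance_components(model)
        assert vc["discharge_only"]["adj_r2"] > 0.8
        assert vc["lulc_only"]["adj_r2"] < vc["discharge_only"]["adj_r2"]


class TestDiagnostics:
    def test_vif_matches_manual_regression(self, noisy):
        fit = noisy.fit()
        diag = diagnostics(noisy, fit)
        X, names = noisy.design(fit.params.r)
        Xs = X[:, 1:]
        j = 0  # check the lnQ column by explicit regression
        others = np.column_stack([np.ones(noisy.M), Xs[:, 1:]])
        beta, *_ = np.linalg.lstsq(others, Xs[:, j], rcond=None)
        resid = Xs[:, j] - others @ beta
        r2 = 1 - resid @ resid / ((Xs[:, j] - Xs[:, j].mean()) ** 2).sum()
        assert diag["vif"][names[1]] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_residuals_plus_fitted_reconstruct_observations(self, noisy):
        fit = noisy.fit()
        np.testing.assert_allclose(fit.fitted + fit.residuals, noisy.B,
                                   atol=1e-10)

    def test_correlation_matrix_shape(self, noisy):
        diag = diagnostics(noisy, noisy.fit())
        corr = diag["correlations"]
        assert corr.shape[0] == corr.shape[1] == len(diag["vif"])
        np.testing.assert_allclose(np.diag(corr), 1.0)


class TestRegionSplit:
    def test_full_filter_identical_to_full_fit(self, noisy):
        full = noisy.fit()
        split = fit_region_split(noisy, np.ones(noisy.M, dtype=bool))
        assert split.loglik == pytest.approx(full.loglik, rel=1e-9)
        assert split.params.r == pytest.approx(full.params.r, rel=1e-6)

    def test_too_few_sites_rejected(self, noisy):
        mask = np.zeros(noisy.M, dtype=bool)
        mask[:3] = True
        with pytest.raises(ValueError):
            fit_region_split(noisy, mask)


def test_fit_mle_wrapper(small_landscape, truth):
    obs, _ = generate_observations(small_landscape, truth, sigma=2.0, seed=51)
    fit = fit_mle(obs, small_landscape.fields, small_landscape.lulc,
                  small_landscape.areas, compute_tests=True)
    assert np.isfinite(fit.minus2l)
    assert set(fit.p_values) >= {"b", "r"}


class TestCountLikelihoods:
    def test_poisson_fit_recovers_signal_direction(self, small_landscape,
                                                   truth):
        from fishdiv.richness import fit_count_model
        obs, _ = generate_observations(small_landscape, truth, sigma=0.0,
                                       seed=71, round_to_int=True)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        out = fit_count_model(model, family="poisson")
        assert np.isfinite(out["loglik"])
        assert out["b"] > 0  # discharge raises expected richness in truth

    def test_negbin_adds_dispersion(self, small_landscape, truth):
        from fishdiv.richness import fit_count_model
        obs, _ = generate_observations(small_landscape, truth, sigma=5.0,
                                       seed=72, round_to_int=True)
        model = RichnessModel(B=obs["richness"], Q=obs["discharge"],
                              fields=small_landscape.fields,
                              lulc=small_landscape.lulc,
                              areas=small_landscape.areas)
        out = fit_count_model(model, family="negbin", n_grid=10)
        assert out["dispersion"] is not None and out["dispersion"] > 0
        assert np.isfinite(out["loglik"])
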