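"""Tests of the bridge-distribution simulator and missingness machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid, quad
from scipy.special import expit, logit
from scipy.stats import kstest, spearmanr

import ordmi
from ordmi import (
    GenerativeSpec,
    apply_missingness,
    bridge_density,
    bridge_quantile,
    bridge_variance,
    calibrate_alpha0,
    default_aux_models,
    draw_cluster_effects,
    draw_cluster_sizes,
    fit_cwgee,
    make_missingness_model,
    read_panel,
    simulate_full_table,
    validate_panel,
    write_panel,
)
from ordmi.simulate import calibrated

from _oracles import cwgee_estimating_function  # noqa: F401  (shared test helpers importable)


class TestBridgeDistribution:
    @pytest.mark.parametrize("phi", [0.2, 0.5, 0.9])
    def test_median_is_zero(self, phi):
        assert bridge_quantile(0.5, phi) == pytest.approx(0.0, abs=1e-12)

    def test_density_integrates_to_one(self):
        val, _ = quad(lambda b: bridge_density(b, 0.7), -40, 40)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_quantile_variance_matches_quadrature(self, rng):
        # oracle: second moment of the density by adaptive quadrature
        var_quad, _ = quad(lambda b: b * b * bridge_density(b, 0.5), -80, 80)
        draws = bridge_quantile(rng.random(10**6), 0.5)
        assert draws.var() == pytest.approx(var_quad, rel=0.01)
        assert bridge_variance(0.5) == pytest.approx(var_quad, rel=1e-8)

    def test_quantile_transform_matches_density_cdf(self, rng):
        grid = np.linspace(-60, 60, 4001)
        cdf = cumulative_trapezoid(bridge_density(grid, 0.7), grid, initial=0.0)
        cdf /= cdf[-1]
        draws = bridge_quantile(rng.random(20000), 0.7)
        res = kstest(draws, lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01

    @pytest.mark.parametrize("bad_u", [0.0, 1.0, -0.2, 1.7])
    def test_rejects_u_outside_unit_interval(self, bad_u):
        with pytest.raises(ValueError):
            bridge_quantile(bad_u, 0.5)

    @pytest.mark.parametrize("bad_phi", [0.0, 1.0, -1.0, 2.0])
    def test_rejects_phi_outside_unit_interval(self, bad_phi):
        with pytest.raises(ValueError):
            bridge_quantile(0.3, bad_phi)


class TestClusterEffects:
    def test_independent_when_icc_zero(self, rng):
        spec = GenerativeSpec(n_clusters=10_000, icc=0.0)
        b = draw_cluster_effects(spec, rng)
        cov = np.cov(b, rowvar=False)
        off = cov[~np.eye(cov.shape[0], dtype=bool)]
        corr = off.mean() / np.diag(cov).mean()
        assert abs(corr) < 0.02

    def test_marginal_variance_matches_formula(self, rng):
        spec = GenerativeSpec(n_clusters=10_000, icc=0.3)
        b = draw_cluster_effects(spec, rng)
        assert b.var() == pytest.approx(bridge_variance(0.5), rel=0.02)

    def test_exchangeable_pairwise_correlation(self, rng):
        # any two member positions should be equally correlated
        spec = GenerativeSpec(n_clusters=20_000, icc=0.3)
        b = draw_cluster_effects(spec, rng)
        r_adjacent = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
        r_distant = np.corrcoef(b[:, 0], b[:, 27])[0, 1]
        assert r_adjacent == pytest.approx(r_distant, abs=0.03)
        assert r_adjacent > 0.2


class TestClusterSizes:
    def test_mean_size_half_max_without_ics(self, rng):
        spec = GenerativeSpec(n_clusters=10_000, ics_degree=0.0)
        b = draw_cluster_effects(spec, rng)
        sizes = draw_cluster_sizes(b, 0.0, 28, rng)
        assert sizes.mean() == pytest.approx(14.0, rel=0.01)

    def test_sizes_within_bounds(self, rng):
        spec = GenerativeSpec(n_clusters=5_000, ics_degree=0.4)
        b = draw_cluster_effects(spec, rng)
        sizes = draw_cluster_sizes(b, 0.4, 28, rng)
        assert sizes.min() >= 1 and sizes.max() <= 28

    def test_ics_links_size_to_latent_health(self, rng):
        spec = GenerativeSpec(n_clusters=10_000, ics_degree=0.4)
        b = draw_cluster_effects(spec, rng)
        sizes = draw_cluster_sizes(b, 0.4, 28, rng)
        rho = spearmanr(sizes, b.mean(axis=1)).statistic
        assert rho > 0.3


class TestSimulateFullTable:
    def test_marginal_category_probabilities_closed_form(self, rng):
        # marginalising the bridge effect must return the proportional-odds
        # model: category probabilities at x = z = 0 follow from eta alone
        eta = np.array([-0.4, 0.8, 1.6])
        b = bridge_quantile(rng.random(10**6), 0.5)
        marg = np.array([expit(b + e / 0.5).mean() for e in eta])
        expected_cum = expit(eta)
        np.testing.assert_allclose(marg, expected_cum, atol=1e-3)
        probs = np.diff(np.concatenate([[0.0], expected_cum, [1.0]]))
        np.testing.assert_allclose(probs, [0.4013, 0.2889, 0.1418, 0.1680], atol=1e-3)

    def test_category_frequencies_without_covariate_effects(self, rng):
        spec = GenerativeSpec(n_clusters=3_000, beta=(0.0, 0.0), icc=0.3, ics_degree=0.0)
        tab = simulate_full_table(spec, rng)
        freq = tab["y"].value_counts(normalize=True).sort_index().to_numpy()
        np.testing.assert_allclose(freq, [0.4013, 0.2889, 0.1418, 0.1680], atol=0.01)

    def test_cwgee_recovers_generating_parameters(self, rng):
        spec = GenerativeSpec(n_clusters=2_000, icc=0.3, ics_degree=0.4)
        tab = simulate_full_table(spec, rng)
        fit = fit_cwgee(tab, 4)
        truth = np.array([-0.4, 0.8, 1.6, -0.2, -0.5])
        diff = fit.coefficients - truth
        mahal = diff @ np.linalg.solve(fit.robust_vcov, diff)
        # joint 99.9% chi-square(5) region
        assert mahal < 20.5

    def test_ics_direction_on_outcome(self, rng):
        spec = GenerativeSpec(n_clusters=5_000, ics_degree=0.4)
        tab = simulate_full_table(spec, rng)
        per = tab.groupby("cluster").agg(size=("y", "size"), ymean=("y", "mean"))
        assert spearmanr(per["size"], per["ymean"]).statistic < -0.1

        spec0 = GenerativeSpec(n_clusters=5_000, ics_degree=0.0)
        tab0 = simulate_full_table(spec0, rng)
        per0 = tab0.groupby("cluster").agg(size=("y", "size"), ymean=("y", "mean"))
        assert abs(spearmanr(per0["size"], per0["ymean"]).statistic) < 0.05

    def test_reproducible_given_seed(self):
        spec = GenerativeSpec(n_clusters=30)
        t1 = simulate_full_table(spec, np.random.default_rng(123))
        t2 = simulate_full_table(spec, np.random.default_rng(123))
        pd.testing.assert_frame_equal(t1, t2)

    def test_panel_invariants(self, small_table):
        validate_panel(small_table, n_categories=4, max_size=28)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GenerativeSpec(eta=(0.5, 0.1, 1.0))  # non-increasing cutpoints
        with pytest.raises(ValueError):
            GenerativeSpec(bridge_phi=1.2)
        with pytest.raises(ValueError):
            GenerativeSpec(icc=0.8)  # copula correlation would exceed 1


class TestMissingness:
    def test_intercept_only_calibration_is_logit(self, small_table):
        model = make_missingness_model("mcar", 0.2)
        a0 = calibrate_alpha0(model, [small_table])
        assert a0 == pytest.approx(logit(0.2), abs=1e-8)

    def test_alpha0_increasing_in_target(self, small_table):
        model = make_missingness_model("mar", 0.2)
        a02 = calibrate_alpha0(model, [small_table], target_rate=0.2)
        a05 = calibrate_alpha0(model, [small_table], target_rate=0.5)
        assert a05 > a02

    def test_realized_rate_matches_target(self):
        spec = GenerativeSpec(n_clusters=250)
        rng = np.random.default_rng(5)
        pilots = [simulate_full_table(spec, rng) for _ in range(20)]
        model = calibrated(make_missingness_model("mar", 0.5), pilots)
        aux = tuple(calibrated(m, pilots) for m in default_aux_models())
        rates = []
        for _ in range(100):
            tab = simulate_full_table(spec, rng)
            amp = apply_missingness(tab, model, aux, rng)
            rates.append(amp["y"].isna().mean())
        assert 0.49 <= np.mean(rates) <= 0.51

    def test_auxiliary_rates_hit_targets(self):
        spec = GenerativeSpec()
        rng = np.random.default_rng(11)
        pilots = [simulate_full_table(spec, rng) for _ in range(30)]
        model = calibrated(make_missingness_model("mar", 0.2), pilots)
        aux = tuple(calibrated(m, pilots) for m in default_aux_models())
        sums = np.zeros(3)
        n_tables = 200
        for _ in range(n_tables):
            tab = simulate_full_table(spec, rng)
            amp = apply_missingness(tab, model, aux, rng)
            sums += [amp[c].isna().mean() for c in ("m1", "m2", "m3")]
        np.testing.assert_allclose(sums / n_tables, [0.30, 0.30, 0.10], atol=0.015)

    def test_no_missingness_identity(self, small_table, rng):
        model = make_missingness_model("mar", 0.2)
        model = ordmi.MissingnessModel(
            mechanism=model.mechanism,
            target_rate=model.target_rate,
            alphas=model.alphas,
            alpha0=-np.inf,
        )
        aux = tuple(
            ordmi.MissingnessModel(m.mechanism, m.target_rate, m.alphas, -np.inf)
            for m in default_aux_models()
        )
        amp = apply_missingness(small_table, model, aux, rng)
        for col in ("y", "m1", "m2", "m3"):
            assert amp[col].notna().all()
            np.testing.assert_array_equal(amp[col], small_table[col])

    def test_mcar_rates_independent_of_category(self, rng):
        spec = GenerativeSpec(n_clusters=4_000)
        tab = simulate_full_table(spec, rng)
        model = calibrated(make_missingness_model("mcar", 0.2), [tab])
        aux = tuple(calibrated(m, [tab]) for m in default_aux_models())
        amp = apply_missingness(tab, model, aux, rng)
        miss = amp["y"].isna().to_numpy()
        rates = [miss[tab["y"] == c].mean() for c in range(1, 5)]
        assert max(rates) - min(rates) < 0.02

    def test_mar_rates_increase_with_category(self, rng):
        spec = GenerativeSpec(n_clusters=4_000)
        tab = simulate_full_table(spec, rng)
        model = calibrated(make_missingness_model("mar", 0.2), [tab])
        aux = tuple(calibrated(m, [tab]) for m in default_aux_models())
        amp = apply_missingness(tab, model, aux, rng)
        miss = amp["y"].isna().to_numpy()
        rates = [miss[tab["y"] == c].mean() for c in range(1, 5)]
        assert np.all(np.diff(rates) > 0)

    def test_mechanism_slope_consistency(self):
        assert np.all(np.asarray(make_missingness_model("mcar", 0.2).alphas) == 0)
        assert make_missingness_model("mar", 0.2).alphas[2] == 0
        assert make_missingness_model("mnar", 0.2).alphas[2] != 0
        with pytest.raises(ValueError):
            ordmi.MissingnessModel("mcar", 0.2, alphas=(0.1, 0, 0, 0, 0, 0))


class TestPanelIO:
    def test_csv_round_trip_preserves_missing(self, small_table, rng, tmp_path):
        model = calibrated(make_missingness_model("mar", 0.2), [small_table])
        aux = tuple(calibrated(m, [small_table]) for m in default_aux_models())
        amp = apply_missingness(small_table, model, aux, rng)
        path = tmp_path / "panel.csv"
        write_panel(amp, path)
        back = read_panel(path)
        for col in ("y", "m1", "m2", "m3", "x", "z"):
            np.testing.assert_array_equal(
                back[col].isna().to_numpy(), amp[col].isna().to_numpy()
            )
            np.testing.assert_allclose(
                back[col].dropna().to_numpy(), amp[col].dropna().to_numpy()
            )

    def test_validate_rejects_varying_level2_covariate(self, small_table):
        broken = small_table.copy()
        broken.loc[broken.index[0], "x"] += 1.0
        with pytest.raises(ValueError):
            validate_panel(broken, n_categories=4)
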