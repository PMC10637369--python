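"""Quasi-Poisson fitting, effect transforms, subgroups and two-pollutant models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.discrete.conditional_models import ConditionalPoisson

from aircrossover.datamodel import DailySeries
from aircrossover.design import LagSpec, apply_lag, make_strata
from aircrossover.estimation import (
    FitError,
    ModelSpec,
    collinearity_screen,
    compare_subgroups,
    effect_from_fit,
    er_curve,
    fit_quasipoisson,
    fit_two_pollutant,
    invert_percent_change,
    lag_profile,
    percent_change,
)
from aircrossover.simulate import ScenarioConfig, generate_scenario

TOY_SPEC = ModelSpec(
    outcome="deaths_all_cause",
    exposure="pm25",
    lag=LagSpec.single(0),
    confounder_dfs={},
    extra_covariates=(),
)

MAIN_SPEC = ModelSpec(outcome="deaths_all_cause", exposure="pm25")


class TestFitQuasipoisson:
    def test_closed_form_binary_toy(self, toy_series):
        """Saturated binary design: MLE is the log ratio of exposed/unexposed sums."""
        fit = fit_quasipoisson(toy_series, TOY_SPEC)
        assert fit.beta == pytest.approx(np.log(21 / 11), abs=1e-6)

    def test_fixed_effects_match_conditional_likelihood(self, toy_series):
        """Stratum indicators and conditioning give the same Poisson beta."""
        fit = fit_quasipoisson(toy_series, TOY_SPEC)
        f = toy_series.frame
        strata = make_strata(f.index).labels
        informative = f["deaths_all_cause"].groupby(strata).transform("sum") > 0
        cond = ConditionalPoisson(
            f.loc[informative, "deaths_all_cause"],
            f.loc[informative, ["pm25"]],
            groups=strata[informative],
        ).fit(disp=0)
        assert fit.beta == pytest.approx(float(cond.params.iloc[0]), abs=1e-6)

    def test_dispersion_near_one_for_poisson_data(self):
        cfg = ScenarioConfig(rng_seed=5, overdispersion=1.0)
        fit = fit_quasipoisson(generate_scenario(cfg), MAIN_SPEC)
        assert 0.9 <= fit.dispersion <= 1.1

    def test_beta_recovery_single_scenario(self, default_series):
        """The injected ma03 effect lands inside its own 95% CI."""
        fit = fit_quasipoisson(default_series, MAIN_SPEC)
        truth = default_series.metadata["true_log_rr_per_ug"]["pm25"]
        assert abs(fit.beta - truth) < 1.96 * fit.se

    def test_constant_exposure_reported_not_crashed(self, toy_series):
        toy = toy_series.subset(pd.Series(True, index=toy_series.dates))
        toy.frame["pm25"] = 5.0
        with pytest.raises(FitError, match="collinear|aliased"):
            fit_quasipoisson(toy, TOY_SPEC)

    def test_count_scaling_moves_dispersion_not_beta(self, default_series):
        """Scaling counts k-fold multiplies phi by ~k and leaves beta alone."""
        k = 4
        scaled = default_series.subset(pd.Series(True, index=default_series.dates))
        scaled.frame["deaths_all_cause"] = k * scaled.frame["deaths_all_cause"]
        f1 = fit_quasipoisson(default_series, MAIN_SPEC)
        f2 = fit_quasipoisson(scaled, MAIN_SPEC)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-8)
        assert f2.dispersion / f1.dispersion == pytest.approx(k, rel=0.02)
        # sqrt(phi) inflation exactly offsets the k-fold information gain
        assert f2.se / f1.se == pytest.approx(1.0, rel=1e-6)

    def test_covariance_is_symmetric_psd(self, default_series):
        fit = fit_quasipoisson(default_series, MAIN_SPEC)
        C = fit.cov.to_numpy()
        assert np.allclose(C, C.T, atol=1e-10)
        assert np.linalg.eigvalsh(C).min() > -1e-8
        assert fit.dispersion > 0

    def test_time_spline_control_agrees_with_strata(self, default_series):
        spline_spec = ModelSpec(
            outcome="deaths_all_cause", exposure="pm25",
            time_control="spline", time_spline_df_per_year=7,
        )
        f1 = fit_quasipoisson(default_series, MAIN_SPEC)
        f2 = fit_quasipoisson(default_series, spline_spec)
        # CIs overlap: the two time-control modes see the same signal
        assert f1.beta - 1.96 * f1.se < f2.beta + 1.96 * f2.se
        assert f2.beta - 1.96 * f2.se < f1.beta + 1.96 * f1.se


class TestPercentChange:
    def test_null_beta(self):
        eff = percent_change(0.0, 0.001)
        assert eff.percent == 0.0
        assert eff.ci_low == pytest.approx(-eff.ci_high / (1 + eff.ci_high / 100), rel=1e-6)

    def test_worked_example(self):
        eff = percent_change(0.001, 0.0005, delta=10)
        assert eff.percent == pytest.approx(1.005, abs=1e-3)
        assert eff.ci_low == pytest.approx(0.020, abs=1e-3)
        assert eff.ci_high == pytest.approx(2.000, abs=1e-3)

    def test_reported_estimate_roundtrip(self):
        """Back-solved (beta, se) reproduce a published 2.00% (1.08-2.92)."""
        beta, se = invert_percent_change(2.00, 1.08, 2.92)
        eff = percent_change(beta, se)
        assert round(eff.percent, 2) == 2.00
        assert round(eff.ci_low, 2) == 1.08
        assert round(eff.ci_high, 2) == 2.92

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        beta=st.floats(min_value=-0.01, max_value=0.01),
        se=st.floats(min_value=0.0, max_value=0.005),
    )
    def test_monotone_in_beta_and_invertible(self, beta, se):
        eff = percent_change(beta, se)
        bigger = percent_change(beta + 1e-4, se)
        assert bigger.percent > eff.percent
        back = np.log(1 + eff.percent / 100) / 10
        assert back == pytest.approx(beta, abs=1e-12)


class TestLagProfile:
    def test_recovers_injected_lag_structure(self):
        """Weights concentrated at lags 1-2 peak the single-lag profile there."""
        cfg = ScenarioConfig(
            rng_seed=21,
            true_log_rr_per_ug={"pm25": 0.003},
            lag_weights=(0.10, 0.45, 0.35, 0.10),
        )
        series = generate_scenario(cfg)
        prof = lag_profile(series, MAIN_SPEC)
        assert prof.peak_single_lag() in (1, 2)
        assert "ma03" in prof.estimates
        assert not prof.errors


class TestErCurve:
    def test_df1_equals_linear_fit(self, default_series):
        fit = fit_quasipoisson(default_series, MAIN_SPEC)
        curve = er_curve(default_series, MAIN_SPEC, df=1)
        expected = fit.beta * (curve.grid - curve.reference)
        assert np.allclose(curve.log_rr, expected, atol=1e-6)

    def test_reference_is_zero(self, default_series):
        curve = er_curve(default_series, MAIN_SPEC, df=3)
        assert curve.log_rr[0] == pytest.approx(0.0, abs=1e-12)
        assert len(curve.grid) >= 50

    def test_df3_vs_df5_within_band(self, default_series):
        """On log-linear truth the curve is stable across spline dfs."""
        c3 = er_curve(default_series, MAIN_SPEC, df=3)
        c5 = er_curve(default_series, MAIN_SPEC, df=5)
        band_width = c3.ci_high - c3.ci_low
        inner = slice(5, 95)
        assert np.max(np.abs(c3.log_rr - c5.log_rr)[inner]) < np.max(band_width[inner])


class TestCompareSubgroups:
    def test_identical_estimates(self, toy_series):
        fit = fit_quasipoisson(toy_series, TOY_SPEC)
        cmp = compare_subgroups(fit, fit)
        assert cmp.z == 0.0
        assert cmp.p_value == 1.0

    def test_worked_example(self):
        from aircrossover.estimation import FitResult

        def fake(beta, se):
            params = pd.Series({"x": beta})
            cov = pd.DataFrame([[se**2]], index=["x"], columns=["x"])
            return FitResult(params, cov, 1.0, 100, "x", TOY_SPEC, True, 0)

        cmp = compare_subgroups(fake(0.02, 0.005), fake(0.01, 0.005))
        assert cmp.z == pytest.approx(1.4142, abs=1e-3)
        assert cmp.p_value == pytest.approx(0.1573, abs=1e-3)

    def test_zero_ses_rejected(self):
        from aircrossover.estimation import FitResult

        params = pd.Series({"x": 0.1})
        cov = pd.DataFrame([[0.0]], index=["x"], columns=["x"])
        fr = FitResult(params, cov, 1.0, 10, "x", TOY_SPEC, True, 0)
        with pytest.raises(ValueError, match="zero"):
            compare_subgroups(fr, fr)


class TestCollinearityScreen:
    def test_identical_series_excluded(self, default_series):
        s = default_series.subset(pd.Series(True, index=default_series.dates))
        s.frame["pm25_copy"] = s.frame["pm25"]
        screen = collinearity_screen(s, ["pm25", "pm25_copy"])
        assert screen.rho[("pm25", "pm25_copy")] == pytest.approx(1.0)
        assert ("pm25", "pm25_copy") in screen.excluded

    def test_independent_noise_admitted(self):
        rng = np.random.default_rng(8)
        dates = pd.date_range("2014-01-01", periods=1000, freq="D")
        f = pd.DataFrame(
            {"pm25": rng.uniform(size=1000) * 50, "o3": rng.uniform(size=1000) * 50},
            index=dates,
        )
        f.index.name = "date"
        screen = collinearity_screen(DailySeries(f), ["pm25", "o3"])
        assert abs(screen.rho[("pm25", "o3")]) < 0.1
        assert ("pm25", "o3") in screen.admissible

    def test_simulated_no2_pair_excluded(self, default_series):
        """The generator's NO2 tracks PM closely enough to fail the screen."""
        screen = collinearity_screen(default_series)
        assert not screen.is_admissible("pm25", "no2")
        assert screen.is_admissible("pm25", "o3")

    def test_constant_series_skipped(self, default_series):
        s = default_series.subset(pd.Series(True, index=default_series.dates))
        s.frame["flat"] = 1.0
        screen = collinearity_screen(s, ["pm25", "flat"])
        assert ("pm25", "flat") in screen.skipped


class TestTwoPollutant:
    def test_exact_copy_refused(self, default_series):
        s = default_series.subset(pd.Series(True, index=default_series.dates))
        s.frame["pm25_copy"] = s.frame["pm25"]
        with pytest.raises(ValueError, match="rho"):
            fit_two_pollutant(s, MAIN_SPEC, "pm25_copy")

    def test_independent_copollutant_small_shift(self, default_series):
        """Adding near-orthogonal O3 moves the primary beta by < 1 SE."""
        single = fit_quasipoisson(default_series, MAIN_SPEC)
        double = fit_two_pollutant(default_series, MAIN_SPEC, "o3")
        assert abs(double.beta - single.beta) < single.se
        truth = default_series.metadata["true_log_rr_per_ug"]["pm25"]
        assert abs(double.beta - truth) < 1.96 * double.se
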