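"""Anomalies, dominant-driver classification, factor-constant decomposition."""
import numpy as np
import pandas as pd
import pytest
import xarray as xr

import wetch4 as w
from wetch4.attribution import (DRIVER_ORDER, GROUP_ORDER, annual_anomaly,
                                attribute_trend, dominance_map, dominant_driver,
                                factor_constant_decomposition,
                                fit_all_factor_model, group_indices,
                                regional_dominance_summary, sidak_level)
from wetch4.errors import DegenerateInputError, InvalidConfigError
from wetch4.synthetic_data import planted_dominance_scene


class TestAnnualAnomaly:
    def test_linear_series_maps_to_zero(self):
        assert np.allclose(annual_anomaly(3.0 * np.arange(20) + 7.0), 0.0, atol=1e-9)

    def test_idempotent(self, rng):
        y = rng.standard_normal(20)
        a = annual_anomaly(y)
        np.testing.assert_allclose(annual_anomaly(a), a, atol=1e-12)

    def test_mean_and_slope_removed(self, rng):
        a = annual_anomaly(np.cumsum(rng.standard_normal(20)))
        t = np.arange(20, dtype=float)
        assert abs(a.mean()) < 1e-9
        assert abs(np.polyfit(t, a, 1)[0]) < 1e-9

    def test_matches_explicit_ols_oracle(self, rng):
        t = np.arange(20, dtype=float)
        y = np.sin(t / 3.0) + 0.4 * t + 2.0
        X = np.column_stack([np.ones(20), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(annual_anomaly(y), y - X @ beta, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidConfigError):
            annual_anomaly([1.0, 2.0])


class TestDominantDriver:
    def test_planted_dominance_recovered(self):
        flux, drivers, truth = planted_dominance_scene(n_cells=100, effect=1.0,
                                                      noise_sd=0.3, seed=4)
        correct = 0
        for c in range(100):
            anoms = {d: annual_anomaly(v[c]) for d, v in drivers.items()}
            winner, group, sig, rho, p = dominant_driver(annual_anomaly(flux[c]), anoms)
            correct += winner == truth[c]
        assert correct >= 95

    def test_group_mapping(self):
        flux, drivers, truth = planted_dominance_scene(n_cells=10, frac_ts=1.0,
                                                      effect=2.0, noise_sd=0.1, seed=5)
        anoms = {d: annual_anomaly(v[0]) for d, v in drivers.items()}
        winner, group, sig, *_ = dominant_driver(annual_anomaly(flux[0]), anoms)
        assert (winner, group, sig) == ("TS", "temperature", True)

    def test_deterministic_and_tie_break_order_fixed(self, rng):
        # symmetric construction: B is A reversed, flux = A + B, so the two
        # candidates carry identical information; the fixed order must win
        a = rng.standard_normal(24)
        b = a[::-1].copy()
        flux = a + b
        anoms = {"TS": annual_anomaly(a), "TA": annual_anomaly(b)}
        r1 = dominant_driver(annual_anomaly(flux), anoms)
        r2 = dominant_driver(annual_anomaly(flux), anoms)
        assert r1 == r2
        assert r1[0] in ("TS", "TA")

    def test_sidak_level_below_alpha(self):
        assert 0 < sidak_level(0.05, 8) < 0.05 / 7

    def test_too_few_years_rejected(self, rng):
        anoms = {d: rng.standard_normal(8) for d in DRIVER_ORDER}
        with pytest.raises(InvalidConfigError):
            dominant_driver(rng.standard_normal(8), anoms)


class TestFactorModel:
    def regressors(self, rng, n=20):
        ann = {d: np.cumsum(rng.standard_normal(n)) for d in w.DRIVERS}
        return group_indices(ann)

    def test_exact_linear_flux_interpolated(self, rng):
        reg = self.regressors(rng)
        y = 3.0 + 2.0 * reg["temperature"].values - 1.0 * reg["GPP"].values \
            + 0.5 * reg["water"].values + 0.2 * reg["others"].values
        fit = fit_all_factor_model(y, reg)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)
        assert fit["beta"]["temperature"] == pytest.approx(2.0, abs=1e-9)
        assert fit["beta"]["GPP"] == pytest.approx(-1.0, abs=1e-9)

    def test_betas_match_normal_equation_oracle(self, rng):
        reg = self.regressors(rng)
        y = rng.standard_normal(20)
        fit = fit_all_factor_model(y, reg)
        X = np.column_stack([np.ones(20), reg.values])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            [fit["intercept"]] + [fit["beta"][g] for g in reg.columns], beta, atol=1e-10)

    def test_constant_offset_moves_only_intercept(self, rng):
        reg = self.regressors(rng)
        y = rng.standard_normal(20)
        f1 = fit_all_factor_model(y, reg)
        f2 = fit_all_factor_model(y + 10.0, reg)
        assert f2["intercept"] == pytest.approx(f1["intercept"] + 10.0, abs=1e-9)
        for g in reg.columns:
            assert f2["beta"][g] == pytest.approx(f1["beta"][g], abs=1e-9)

    def test_collinear_design_rejected(self, rng):
        reg = self.regressors(rng)
        reg["GPP"] = 2.0 * reg["temperature"]
        with pytest.raises(DegenerateInputError):
            fit_all_factor_model(rng.standard_normal(20), reg)


class TestDecomposition:
    def test_model_difference_equals_coefficient_form(self, rng):
        ann = {d: np.cumsum(rng.standard_normal(20)) for d in w.DRIVERS}
        reg = group_indices(ann)
        y = 1.0 + 0.8 * reg["temperature"].values + 0.3 * rng.standard_normal(20)
        fit = fit_all_factor_model(y, reg)
        dec = factor_constant_decomposition(fit, reg)
        for g in reg.columns:
            x = reg[g].values
            np.testing.assert_allclose(dec.model_all - dec.model_x[g],
                                       fit["beta"][g] * (x - x[0]), atol=1e-12)

    def test_contributions_sum_to_model_all_trend(self, rng):
        ann = {d: np.cumsum(rng.standard_normal(20)) + 0.2 * np.arange(20)
               for d in w.DRIVERS}
        reg = group_indices(ann)
        y = rng.standard_normal(20) + reg["temperature"].values
        fit = fit_all_factor_model(y, reg)
        dec = factor_constant_decomposition(fit, reg)
        assert sum(dec.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_trending_factor_takes_all(self):
        t = np.arange(20, dtype=float)
        reg = pd.DataFrame({
            "temperature": 0.5 * t - 4.0,
            "GPP": np.sin(t),  # varies but trend-free-ish
            "water": np.cos(t / 2),
        })
        y = 2.0 + 1.5 * reg["temperature"].values
        fit = fit_all_factor_model(y, reg)
        dec = factor_constant_decomposition(fit, reg)
        assert dec.percent["temperature"] == pytest.approx(100.0, abs=1.0)
        assert abs(dec.percent["GPP"]) < 1.0 and abs(dec.percent["water"]) < 1.0


class TestGriddedAttribution:
    def test_temperature_dominates_truth_scene(self, scene):
        drivers, wetlands, truth, _ = scene
        dom = dominance_map(truth, drivers, wetlands)
        summary = regional_dominance_summary(dom)
        ba = summary[summary.region == "BA"].iloc[0]
        assert ba["temperature"] > 50.0
        groups = [g for g in GROUP_ORDER]
        assert sum(ba[g] for g in groups) == pytest.approx(100.0, abs=0.1)

    def test_dominance_invariant_to_driver_rescaling(self, scene):
        drivers, wetlands, truth, _ = scene
        dom1 = dominance_map(truth, drivers, wetlands)
        scaled = drivers.copy()
        scaled["TS"] = drivers["TS"] * 10.0 + 100.0
        scaled["P"] = drivers["P"] * 0.001
        dom2 = dominance_map(truth, scaled, wetlands)
        np.testing.assert_array_equal(dom1["winner"].values, dom2["winner"].values)
        np.testing.assert_array_equal(dom1["significant"].values, dom2["significant"].values)

    def test_all_temperature_summary(self):
        coords = {"lat": [60.25, 60.75], "lon": [60.25, 60.75]}
        dom = xr.Dataset(
            {
                "winner": xr.DataArray(np.zeros((2, 2), dtype=np.int16),
                                       dims=("lat", "lon"), coords=coords),
                "group": xr.DataArray(np.zeros((2, 2), dtype=np.int16),
                                      dims=("lat", "lon"), coords=coords),
                "significant": xr.DataArray(np.ones((2, 2), dtype=bool),
                                            dims=("lat", "lon"), coords=coords),
            }
        )
        s = regional_dominance_summary(dom)
        ba = s[s.region == "BA"].iloc[0]
        assert ba["temperature"] == 100.0
        assert ba["GPP"] == 0.0 and ba["water"] == 0.0 and ba["others"] == 0.0

    def test_trend_attribution_aggregates_and_sums(self, scene):
        drivers, wetlands, truth, _ = scene
        summary, betas = attribute_trend(truth, drivers, wetlands)
        ba = summary[summary.region == "BA"]
        assert ba["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        # planted warming + greening: temperature leads, GPP second
        byg = ba.set_index("group")["percent"]
        assert byg["temperature"] > byg["GPP"] > byg["water"]
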