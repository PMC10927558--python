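"""Partial correlation and PCMCI: oracle equivalence, calibration, recovery."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import wetch4 as w
from wetch4.causal_graph import (TimeSeriesPanel, infer_graph, mci_tests,
                                 partial_correlation, pc_parent_selection)
from wetch4.errors import (DegenerateInputError, InsufficientDataError,
                           InvalidConfigError)
from wetch4.synthetic_data import ar1_panel


def residual_oracle(x, y, cond):
    """Independent residual-on-residual computation via the normal equations."""
    n = len(x)
    Z = np.column_stack([np.ones(n)] + list(cond))
    bx = np.linalg.solve(Z.T @ Z, Z.T @ x)
    by = np.linalg.solve(Z.T @ Z, Z.T @ y)
    rx, ry = x - Z @ bx, y - Z @ by
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def make_panel(arrays: dict, flux: np.ndarray) -> TimeSeriesPanel:
    idx = pd.date_range("2002-01-01", periods=len(flux), freq="7D")
    return TimeSeriesPanel({"s1": pd.DataFrame({**arrays, "flux": flux}, index=idx)})


class TestPartialCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        rho, p = partial_correlation(x, x)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_empty_conditioning_matches_pearson(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal((2, 80))
            rho, p = partial_correlation(x, y)
            ref = stats.pearsonr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_explicit_residual_oracle(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 4))
            x, y = rng.standard_normal((2, 120))
            cond = list(rng.standard_normal((k, 120)))
            rho, _ = partial_correlation(x, y, cond)
            assert rho == pytest.approx(residual_oracle(x, y, cond), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, z1, z2 = rng.standard_normal((4, 200))
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        rho, p = partial_correlation(x, y, [z1, z2])
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-7)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-7)

    def test_conditioning_removes_common_driver(self):
        # chain z -> x, z -> y: conditioning on z must kill the correlation
        crit = stats.t.ppf(0.975, 500 - 3)
        crit_rho = crit / np.sqrt(500 - 3 + crit**2)
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            z = rng.standard_normal(500)
            x = z + 0.5 * rng.standard_normal(500)
            y = z + 0.5 * rng.standard_normal(500)
            rho, _ = partial_correlation(x, y, [z])
            hits += abs(rho) < crit_rho
        assert hits >= 90

    def test_symmetric_in_x_and_y(self, rng):
        x, y, z = rng.standard_normal((3, 60))
        assert partial_correlation(x, y, [z]) == partial_correlation(y, x, [z])

    def test_constant_residuals_raise(self, rng):
        z = rng.standard_normal(40)
        with pytest.raises(DegenerateInputError):
            partial_correlation(2.0 * z + 1.0, rng.standard_normal(40), [z])

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            partial_correlation([1.0, 2.0], [2.0, 1.0], [[0.0, 1.0]])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50.0), shift=st.floats(-5, 5))
def test_affine_invariance_property(seed, scale, shift):
    """rho and p are invariant to affine rescaling of either argument."""
    rng = np.random.default_rng(seed)
    x, y, z = rng.standard_normal((3, 50))
    base = partial_correlation(x, y, [z])
    scaled = partial_correlation(scale * x + shift, y, [z])
    assert scaled[0] == pytest.approx(base[0], abs=1e-9)
    assert scaled[1] == pytest.approx(base[1], abs=1e-9)


class TestPCSelection:
    def test_planted_single_parent_always_survives(self):
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            X = ar1_panel(2000, 8, rng=rng)
            drivers = dict(zip(w.DRIVERS, X.T))
            flux = 0.8 * np.roll(drivers["TS"], 1) + 0.3 * rng.standard_normal(2000)
            panel = make_panel(drivers, flux)
            cands = pc_parent_selection(panel, max_lag=8, alpha=0.05)
            assert ("TS", 1) in cands

    def test_max_lag_zero_restricts_search_space(self, rng):
        X = ar1_panel(500, 8, rng=rng)
        flux = 0.8 * X[:, 0] + 0.2 * rng.standard_normal(500)
        panel = make_panel(dict(zip(w.DRIVERS, X.T)), flux)
        cands = pc_parent_selection(panel, max_lag=0, alpha=0.05)
        assert all(lag == 0 for _, lag in cands)

    def test_excessive_lag_raises(self, rng):
        X = ar1_panel(60, 8, rng=rng)
        panel = make_panel(dict(zip(w.DRIVERS, X.T)), rng.standard_normal(60))
        with pytest.raises(InsufficientDataError):
            pc_parent_selection(panel, max_lag=30, alpha=0.05)


class TestMCI:
    def test_two_parent_truth_recovered(self):
        rng = np.random.default_rng(77)
        X = ar1_panel(4000, 8, rng=rng)
        drivers = dict(zip(w.DRIVERS, X.T))
        flux = 0.8 * drivers["TS"] + 0.6 * np.roll(drivers["GPP"], 2) \
            + 0.3 * rng.standard_normal(4000)
        g = infer_graph(make_panel(drivers, flux), max_lag=8, alpha=0.05)
        assert set(g.pairs()) == {("TS", 0), ("GPP", 2)}

    def test_confounded_link_rejected(self):
        # TA drives both GPP and flux; GPP has no direct effect
        rng = np.random.default_rng(78)
        X = ar1_panel(4000, 8, rng=rng)
        drivers = dict(zip(w.DRIVERS, X.T))
        drivers["GPP"] = 0.7 * drivers["TA"] + 0.5 * rng.standard_normal(4000)
        flux = 0.8 * drivers["TA"] + 0.3 * rng.standard_normal(4000)
        g = infer_graph(make_panel(drivers, flux), max_lag=8, alpha=0.05)
        assert ("TA", 0) in g.pairs()
        assert all(d != "GPP" for d, _ in g.pairs())

    def test_empty_candidates_give_empty_graph(self, rng):
        X = ar1_panel(300, 8, rng=rng)
        panel = make_panel(dict(zip(w.DRIVERS, X.T)), rng.standard_normal(300))
        g = mci_tests(panel, [], max_lag=8)
        assert g.links == []

    def test_identical_data_identical_graph(self, rng):
        X = ar1_panel(800, 8, rng=rng)
        drivers = dict(zip(w.DRIVERS, X.T))
        flux = 0.8 * drivers["TS"] + 0.3 * rng.standard_normal(800)
        panel = make_panel(drivers, flux)
        g1 = infer_graph(panel, 8, 0.05)
        g2 = infer_graph(panel, 8, 0.05)
        assert [(l.driver, l.lag, l.strength, l.p_value) for l in g1.links] == \
               [(l.driver, l.lag, l.strength, l.p_value) for l in g2.links]

    def test_graph_invariant_to_driver_rescaling(self, rng):
        X = ar1_panel(1500, 8, rng=rng)
        drivers = dict(zip(w.DRIVERS, X.T))
        flux = 0.8 * drivers["TS"] + 0.5 * np.roll(drivers["GPP"], 1) \
            + 0.3 * rng.standard_normal(1500)
        g1 = infer_graph(make_panel(drivers, flux), 8, 0.05)
        scaled = {d: (37.0 * v - 11.0 if d in ("TS", "P") else v) for d, v in drivers.items()}
        g2 = infer_graph(make_panel(scaled, flux), 8, 0.05)
        assert g1.pairs() == g2.pairs()
        for l1, l2 in zip(g1.links, g2.links):
            assert l1.strength == pytest.approx(l2.strength, abs=1e-9)


def test_multi_site_panel_lags_do_not_cross_sites(rng):
    """A lagged sample never mixes the end of one site with the start of another."""
    idx1 = pd.date_range("2002-01-01", periods=100, freq="7D")
    idx2 = pd.date_range("2005-01-01", periods=80, freq="7D")
    s1 = pd.DataFrame({**{d: rng.standard_normal(100) for d in w.DRIVERS},
                       "flux": rng.standard_normal(100)}, index=idx1)
    s2 = pd.DataFrame({**{d: rng.standard_normal(80) for d in w.DRIVERS},
                       "flux": rng.standard_normal(80)}, index=idx2)
    panel = TimeSeriesPanel({"a": s1, "b": s2})
    y, X = panel.lagged([("TS", 3)], "flux", start=3)
    assert y.size == (100 - 3) + (80 - 3)
    np.testing.assert_array_equal(X[:97, 0], s1["TS"].values[:-3])
    np.testing.assert_array_equal(X[97:, 0], s2["TS"].values[:-3])


def test_panel_rejects_nans_and_missing_columns(rng):
    idx = pd.date_range("2002-01-01", periods=50, freq="7D")
    df = pd.DataFrame({**{d: rng.standard_normal(50) for d in w.DRIVERS},
                       "flux": rng.standard_normal(50)}, index=idx)
    bad = df.copy()
    bad.iloc[3, 0] = np.nan
    with pytest.raises(InvalidConfigError):
        TimeSeriesPanel({"a": bad})
    with pytest.raises(InvalidConfigError):
        TimeSeriesPanel({"a": df.drop(columns=["GPP"])})
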