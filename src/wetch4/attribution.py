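"""Dominant-driver classification and factor-constant trend decomposition.

Two complementary questions about the upscaled flux field are answered at
the annual scale, per grid cell:

* **Which driver dominates inter-annual variability?** Annual anomalies
  (long-term mean removed, inter-annual linear trend removed) of the flux
  intensity are partially correlated with each driver's anomalies,
  conditioning on the other seven drivers; the driver with the largest
  |partial correlation| wins. Drivers are reported in four groups:
  temperature (TS, TA), GPP, water-related (P, SWC) and others (WS, PA, SC).

* **Which driver group carries the emission trend?** A per-cell OLS model of
  annual flux on group-level indices (Model_all) is re-evaluated with one
  group held at its first-year value (Model_T, Model_GPP, Model_water, ...).
  For a linear model the difference is exactly beta_X * (X(t) - X(first
  year)), so group contributions are additive and their trends sum to the
  Model_all trend with no residual.

Dominance is computed on flux *intensity* (per-m2 emission), not areal
emission, so wetland-area dynamics cannot masquerade as a driver.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .causal_graph import partial_correlation
from .errors import DegenerateInputError, InvalidConfigError
from .grids import DRIVERS, cell_area, region_masks

#: fixed tie-break order for the dominance winner
DRIVER_ORDER = ("TS", "TA", "GPP", "P", "SWC", "WS", "PA", "SC")

DRIVER_GROUPS = {
    "TS": "temperature", "TA": "temperature",
    "GPP": "GPP",
    "P": "water", "SWC": "water",
    "WS": "others", "PA": "others", "SC": "others",
}

GROUP_ORDER = ("temperature", "GPP", "water", "others")

#: group -> member drivers, fixed order
GROUP_MEMBERS = {
    "temperature": ("TS", "TA"),
    "GPP": ("GPP",),
    "water": ("P", "SWC"),
    "others": ("WS", "PA", "SC"),
}


# ---------------------------------------------------------------------------
# anomalies
# ---------------------------------------------------------------------------

def annual_anomaly(series) -> np.ndarray:
    """Demeaned, linearly detrended annual series (mean 0, OLS slope 0).

    Idempotent: re-processing an anomaly series returns it unchanged.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise InvalidConfigError("anomaly needs >= 3 annual values")
    t = np.arange(y.size, dtype=float)
    t = t - t.mean()
    slope = (t @ (y - y.mean())) / (t @ t)
    return y - y.mean() - slope * t


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

def sidak_level(alpha: float, m: int = len(DRIVERS)) -> float:
    """Per-test level giving a family error of ``alpha`` over ``m`` tests."""
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def dominant_driver(
    flux_anom, driver_anoms: dict, alpha: float = 0.05, family_correction: bool = True,
):
    """Winning driver of one cell's inter-annual flux variability.

    ``driver_anoms`` maps driver name -> annual anomaly series. Each
    driver's partial correlation with the flux conditions on the other
    seven. Ties in |rho| break by the fixed order TS, TA, GPP, P, SWC, WS,
    PA, SC. The cell counts as significantly explained when the winner's p
    falls below the Sidak-corrected level (or raw ``alpha`` with
    ``family_correction=False``).

    Returns ``(winner, group, significant, rho, p)``.
    """
    flux_anom = np.asarray(flux_anom, dtype=float)
    n = flux_anom.size
    k = len(driver_anoms) - 1
    # need several residual degrees of freedom beyond the conditioning set,
    # or the partial correlations saturate at +-1 (20 years, 7 conditioning
    # drivers -> df = 11)
    if n < k + 8:
        raise InvalidConfigError(f"{n} annual points too few for {k} conditioning drivers")

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return v / sd if sd > 0 else v

    # standardize so the classification is robust to affine driver rescaling
    flux_anom = z(flux_anom)
    zanoms = {d: z(a) for d, a in driver_anoms.items()}
    best = None
    for d in DRIVER_ORDER:
        if d not in zanoms:
            continue
        cond = [zanoms[o] for o in DRIVER_ORDER if o != d and o in zanoms]
        try:
            # dof_loss=1: the anomalies were linearly detrended beforehand
            rho, p = partial_correlation(zanoms[d], flux_anom, cond, dof_loss=1)
        except DegenerateInputError:
            continue
        if best is None or abs(rho) > abs(best[3]):
            best = (d, DRIVER_GROUPS[d], p, rho)
    if best is None:
        raise DegenerateInputError("all drivers degenerate in this cell")
    winner, group, p, rho = best
    level = sidak_level(alpha, len(driver_anoms)) if family_correction else alpha
    return winner, group, p <= level, rho, p


# ---------------------------------------------------------------------------
# per-cell annual tables from gridded fields
# ---------------------------------------------------------------------------

def annual_cell_table(flux_field: xr.Dataset, drivers: xr.Dataset, wetlands: xr.Dataset):
    """Annual per-wetland-cell series of flux intensity and every driver.

    The cell's flux intensity is the type-fraction-weighted mean of the
    per-type intensities (type fractions sum to 1 on wetland cells).
    Returns ``(cells, years, flux, driver_tables)`` with ``flux`` of shape
    (n_cells, n_years) and ``driver_tables[d]`` alike.
    """
    wfrac = wetlands["wetland_frac"].values
    cells = np.argwhere(wfrac > 0)
    times = pd.DatetimeIndex(flux_field["time"].values)
    years = np.unique(times.year)
    tf = wetlands["type_frac"].values  # (type, lat, lon)
    inten = flux_field["intensity"].values  # (type, time, lat, lon)
    cell_int = np.einsum("ktij,kij->tij", inten, tf)

    # driver cube may carry spin-up steps: align on the flux time axis
    dtimes = pd.DatetimeIndex(drivers["time"].values)
    sel = dtimes.isin(times)

    def annualize(arr_t_ij):
        s = pd.DataFrame(arr_t_ij[:, cells[:, 0], cells[:, 1]], index=times.year)
        return s.groupby(level=0).mean().values.T  # (cells, years)

    flux = annualize(cell_int)
    driver_tables = {d: annualize(drivers[d].values[sel]) for d in DRIVERS}
    return cells, years, flux, driver_tables


def dominance_map(
    flux_field: xr.Dataset, drivers: xr.Dataset, wetlands: xr.Dataset,
    alpha: float = 0.05, family_correction: bool = True,
) -> xr.Dataset:
    """Per-cell dominant driver of inter-annual flux-intensity variability.

    Returns a Dataset with ``winner`` (index into DRIVER_ORDER, -1 outside
    wetlands), ``group`` (index into GROUP_ORDER, -1), and ``significant``.
    """
    cells, years, flux, driver_tables = annual_cell_table(flux_field, drivers, wetlands)
    nla, nlo = wetlands["lat"].size, wetlands["lon"].size
    winner = np.full((nla, nlo), -1, dtype=np.int16)
    group = np.full((nla, nlo), -1, dtype=np.int16)
    signif = np.zeros((nla, nlo), dtype=bool)
    for c, (i, j) in enumerate(cells):
        fa = annual_anomaly(flux[c])
        if np.std(fa) <= 1e-12:
            continue
        anoms = {d: annual_anomaly(driver_tables[d][c]) for d in DRIVERS}
        anoms = {d: a for d, a in anoms.items() if np.std(a) > 1e-12}
        if len(anoms) < 2:
            continue
        w, g, sig, rho, p = dominant_driver(fa, anoms, alpha, family_correction)
        winner[i, j] = DRIVER_ORDER.index(w)
        group[i, j] = GROUP_ORDER.index(g)
        signif[i, j] = sig
    coords = {"lat": wetlands["lat"].values, "lon": wetlands["lon"].values}
    return xr.Dataset(
        {
            "winner": xr.DataArray(winner, dims=("lat", "lon"), coords=coords,
                                   attrs={"codes": ",".join(DRIVER_ORDER)}),
            "group": xr.DataArray(group, dims=("lat", "lon"), coords=coords,
                                  attrs={"codes": ",".join(GROUP_ORDER)}),
            "significant": xr.DataArray(signif, dims=("lat", "lon"), coords=coords),
        },
        attrs={"alpha": alpha, "family_correction": int(family_correction)},
    )


def regional_dominance_summary(dommap: xr.Dataset, regions: dict | None = None) -> pd.DataFrame:
    """Percent of significantly explained wetland cells per group per region."""
    masks = region_masks(dommap["lat"].values, dommap["lon"].values, regions)
    grp = dommap["group"].values
    sig = dommap["significant"].values
    rows = []
    for region, mask in masks.items():
        use = mask & sig & (grp >= 0)
        total = int(use.sum())
        row = {"region": region, "n_cells": total}
        for gi, g in enumerate(GROUP_ORDER):
            row[g] = 100.0 * float((use & (grp == gi)).sum()) / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# factor-constant trend decomposition
# ---------------------------------------------------------------------------

def group_indices(driver_annuals: dict, include_others: bool = True) -> pd.DataFrame:
    """Group-level annual regressors: standardized within-group means.

    Each member driver is z-scored over years, members averaged; this keeps
    TS/TA from entering as a collinear pair.
    """
    groups = GROUP_ORDER if include_others else GROUP_ORDER[:3]
    out = {}
    for g in groups:
        zs = []
        for d in GROUP_MEMBERS[g]:
            y = np.asarray(driver_annuals[d], dtype=float)
            sd = y.std()
            zs.append((y - y.mean()) / sd if sd > 1e-12 else np.zeros_like(y))
        out[g] = np.mean(zs, axis=0)
    return pd.DataFrame(out)


def fit_all_factor_model(flux_annual, regressors: pd.DataFrame) -> dict:
    """Per-cell OLS of annual flux on the group regressors (Model_all).

    Returns ``{"beta": {group: coef}, "intercept", "fitted", "r2"}``.
    Raises DegenerateInputError if the design is numerically collinear
    (condition number > 1e8).
    """
    y = np.asarray(flux_annual, dtype=float)
    X = np.column_stack([np.ones(y.size), regressors.values])
    if np.linalg.cond(X) > 1e8:
        raise DegenerateInputError("collinear group regressors; cell skipped")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "beta": {g: float(b) for g, b in zip(regressors.columns, coef[1:])},
        "intercept": float(coef[0]),
        "fitted": fitted,
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
    }


@dataclass
class TrendDecomposition:
    """Factor-constant decomposition of one cell's (or region's) trend."""

    beta: dict
    model_all: np.ndarray  # fitted annual series
    model_x: dict = field(default_factory=dict)  # group -> counterfactual series
    contribution: dict = field(default_factory=dict)  # group -> beta_X * (X - X[0])
    percent: dict = field(default_factory=dict)  # group -> % of Model_all trend


def factor_constant_decomposition(fit: dict, regressors: pd.DataFrame) -> TrendDecomposition:
    """Hold each group at its first-year value and difference against Model_all.

    For the linear model the two computations of the contribution —
    Model_all - Model_X and beta_X * (X - X[first year]) — are algebraically
    identical; both are produced and the class stores the coefficient form.
    Percent contributions are trends of the contribution series relative to
    the Model_all trend and sum to 100 exactly over all varying groups.
    """
    t = np.arange(len(regressors), dtype=float)

    def slope(y):
        tc = t - t.mean()
        return float((tc @ (y - y.mean())) / (tc @ tc))

    model_all = fit["fitted"]
    total = slope(model_all)
    dec = TrendDecomposition(beta=dict(fit["beta"]), model_all=model_all)
    for g in regressors.columns:
        x = regressors[g].values.astype(float)
        contrib = fit["beta"][g] * (x - x[0])
        dec.model_x[g] = model_all - contrib
        dec.contribution[g] = contrib
        dec.percent[g] = 100.0 * slope(contrib) / total if abs(total) > 1e-300 else np.nan
    return dec


def attribute_trend(
    flux_field: xr.Dataset, drivers: xr.Dataset, wetlands: xr.Dataset,
    include_others: bool = True, regions: dict | None = None,
):
    """Region-level factor-constant trend attribution.

    Fits the per-cell Model_all on flux intensity, converts per-cell
    contribution series to emission space with the cell's wetland-area
    weight, aggregates over each region, and reports percent contributions
    of each group to the regional Model_all trend.

    Returns ``(summary, cell_betas)``: a tidy DataFrame (region, group,
    percent, trend) and an xr.Dataset of per-cell coefficients.
    """
    cells, years, flux, driver_tables = annual_cell_table(flux_field, drivers, wetlands)
    groups = list(GROUP_ORDER if include_others else GROUP_ORDER[:3])
    nla, nlo = wetlands["lat"].size, wetlands["lon"].size
    res = _resolution_of(wetlands)
    area_w = (
        cell_area(wetlands["lat"].values, res)[:, None] * 1e6 * wetlands["wetland_frac"].values
    )  # m2 wetland per cell

    beta_maps = {g: np.full((nla, nlo), np.nan) for g in groups}
    n_years = years.size
    contrib_cells = {g: np.zeros((len(cells), n_years)) for g in groups}
    model_all_cells = np.zeros((len(cells), n_years))
    ok = np.zeros(len(cells), dtype=bool)
    for c, (i, j) in enumerate(cells):
        reg = group_indices({d: driver_tables[d][c] for d in DRIVERS}, include_others)
        try:
            fit = fit_all_factor_model(flux[c], reg)
        except DegenerateInputError:
            continue
        dec = factor_constant_decomposition(fit, reg)
        ok[c] = True
        model_all_cells[c] = dec.model_all
        for g in groups:
            beta_maps[g][i, j] = fit["beta"][g]
            contrib_cells[g][c] = dec.contribution[g]

    masks = region_masks(wetlands["lat"].values, wetlands["lon"].values, regions)
    t = years.astype(float) - float(years[0])
    tc = t - t.mean()

    def slope(y):
        return float((tc @ (y - y.mean())) / (tc @ tc))

    rows = []
    for region, mask in masks.items():
        in_region = mask[cells[:, 0], cells[:, 1]] & ok
        w = area_w[cells[:, 0], cells[:, 1]][in_region]
        if w.size == 0:
            continue
        total_series = (model_all_cells[in_region] * w[:, None]).sum(axis=0)
        total_slope = slope(total_series)
        for g in groups:
            series = (contrib_cells[g][in_region] * w[:, None]).sum(axis=0)
            s = slope(series)
            rows.append({
                "region": region, "group": g, "trend": s,
                "percent": 100.0 * s / total_slope if abs(total_slope) > 1e-300 else np.nan,
            })
    coords = {"lat": wetlands["lat"].values, "lon": wetlands["lon"].values}
    cell_betas = xr.Dataset(
        {f"beta_{g}": xr.DataArray(beta_maps[g], dims=("lat", "lon"), coords=coords)
         for g in groups}
    )
    return pd.DataFrame(rows), cell_betas


def _resolution_of(ds: xr.Dataset) -> float:
    lat = ds["lat"].values
    if lat.size > 1:
        return float(abs(lat[1] - lat[0]))
    lon = ds["lon"].values
    return float(abs(lon[1] - lon[0])) if lon.size > 1 else 0.5
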