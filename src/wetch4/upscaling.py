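"""Grid application of the ensemble, regional totals, trends and seasonality.

Intensities (nmol CH4 m-2 s-1) predicted per wetland type are converted to
per-cell emissions (g CH4 per cell per weekly step) through the spherical
cell area, the cell's wetland fraction and its type partition:

    emission = sum_type intensity_type * area_type[m2] * dt[s]
               * 1e-9 mol/nmol * 16.04 g/mol

Regional annual totals are reported in Tg CH4 yr-1 for the whole domain
('BA'), the two hotspot boxes (WSL, HBL) and the remainder; the across-member
spread of the ensemble gives the annual uncertainty band. Weekly steps are
assigned to calendar months/years by their start date, and year totals use
the true number of steps in each year.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import AlignmentError, InvalidConfigError
from .grids import WETLAND_TYPES, cell_area, region_masks

MOLAR_MASS_CH4 = 16.04  # g mol-1
STEP_SECONDS = 7 * 86400.0
G_PER_NMOL = 1e-9 * MOLAR_MASS_CH4
TG_PER_G = 1e-12


# ---------------------------------------------------------------------------
# intensity -> emission
# ---------------------------------------------------------------------------

def type_area_m2(wetlands: xr.Dataset) -> xr.DataArray:
    """Wetland area per type per cell, m^2, shape (wetland_type, lat, lon)."""
    areas_km2 = cell_area(wetlands["lat"].values, _resolution(wetlands))
    area = xr.DataArray(areas_km2 * 1e6, dims=("lat",), coords={"lat": wetlands["lat"].values})
    return wetlands["type_frac"] * wetlands["wetland_frac"] * area


def _resolution(ds: xr.Dataset) -> float:
    lat = ds["lat"].values
    if lat.size > 1:
        return float(abs(lat[1] - lat[0]))
    lon = ds["lon"].values
    return float(abs(lon[1] - lon[0])) if lon.size > 1 else 0.5


def emission_from_intensity(intensity: xr.DataArray, wetlands: xr.Dataset) -> xr.DataArray:
    """Per-cell emission (g CH4 per cell per weekly step) from type intensities."""
    if intensity["lat"].size != wetlands["lat"].size or intensity["lon"].size != wetlands["lon"].size:
        raise AlignmentError("intensity and wetland map are on different grids")
    area = type_area_m2(wetlands)
    em = (intensity * area).sum("wetland_type") * STEP_SECONDS * G_PER_NMOL
    em.attrs["units"] = "g CH4 cell-1 step-1"
    return em


# ---------------------------------------------------------------------------
# ensemble prediction over the grid
# ---------------------------------------------------------------------------

def predict_grid(
    models: dict,
    drivers: xr.Dataset,
    wetlands: xr.Dataset,
    keep_members: bool = False,
) -> xr.Dataset:
    """Apply per-type model ensembles cell-wise over the grid.

    ``models`` maps wetland type -> list of TrainedModel. The cube's
    spin-up steps provide lag history; the output covers the analysis
    window. Member predictions are truncated at zero (fluxes are
    emissions); the ensemble mean is the estimate and the member s.d. the
    parameter uncertainty (NaN for a single member). With ``keep_members``
    the per-member emission fields are attached for regional aggregation.
    """
    missing = [wt for wt in WETLAND_TYPES if wt not in models or not models[wt]]
    if missing:
        raise InvalidConfigError(f"no trained model for type(s): {missing}")
    spinup = int(drivers.attrs.get("spinup_weeks", 0))
    max_lag = max(
        (lag for wt in WETLAND_TYPES for _, lag in models[wt][0].pairs), default=0
    )
    t0 = max(spinup, max_lag)
    if t0 > spinup:
        import logging
        logging.getLogger(__name__).warning(
            "lag history exceeds spin-up: first %d analysis steps masked", t0 - spinup
        )
    times = drivers["time"].values[t0:]
    lats, lons = drivers["lat"].values, drivers["lon"].values
    nt, nla, nlo = times.size, lats.size, lons.size
    n_members = len(next(iter(models.values())))

    wfrac = wetlands["wetland_frac"].values
    tfrac = wetlands["type_frac"].values
    inten_mean = np.zeros((len(WETLAND_TYPES), nt, nla, nlo))
    inten_sd = np.zeros_like(inten_mean)
    member_em = np.zeros((n_members, nt, nla, nlo))
    area = type_area_m2(wetlands).values  # (type, lat, lon)

    for k, wt in enumerate(WETLAND_TYPES):
        mods = models[wt]
        cells = np.argwhere((wfrac > 0) & (tfrac[k] > 0))
        if cells.size == 0:
            continue
        pairs = mods[0].pairs
        # feature tensor (cells, time, feature)
        feats = np.empty((len(cells), nt, len(pairs)))
        for f, (d, lag) in enumerate(pairs):
            arr = drivers[d].values  # (T, lat, lon)
            sl = arr[t0 - lag : arr.shape[0] - lag]
            feats[:, :, f] = sl[:, cells[:, 0], cells[:, 1]].T
        flat = feats.reshape(-1, len(pairs))
        preds = np.stack([np.maximum(m.predict(flat), 0.0) for m in mods])
        preds = preds.reshape(n_members, len(cells), nt)
        mean = preds.mean(axis=0)
        sd = preds.std(axis=0, ddof=1) if n_members > 1 else np.full_like(mean, np.nan)
        for c, (i, j) in enumerate(cells):
            inten_mean[k, :, i, j] = mean[c]
            inten_sd[k, :, i, j] = sd[c]
            member_em[:, :, i, j] += (
                preds[:, c, :] * area[k, i, j] * STEP_SECONDS * G_PER_NMOL
            )

    coords = {"time": times, "lat": lats, "lon": lons}
    ds = xr.Dataset(
        {
            "intensity": xr.DataArray(
                inten_mean, dims=("wetland_type", "time", "lat", "lon"),
                coords={"wetland_type": list(WETLAND_TYPES), **coords},
                attrs={"units": "nmol CH4 m-2 s-1"},
            ),
            "intensity_sd": xr.DataArray(
                inten_sd, dims=("wetland_type", "time", "lat", "lon"),
                coords={"wetland_type": list(WETLAND_TYPES), **coords},
                attrs={"units": "nmol CH4 m-2 s-1"},
            ),
        }
    )
    ds["emission"] = emission_from_intensity(ds["intensity"], wetlands)
    ds["emission_sd"] = xr.DataArray(
        member_em.std(axis=0, ddof=1) if n_members > 1 else np.full(member_em.shape[1:], np.nan),
        dims=("time", "lat", "lon"), coords=coords,
        attrs={"units": "g CH4 cell-1 step-1"},
    )
    if keep_members:
        ds["member_emission"] = xr.DataArray(
            member_em, dims=("member", "time", "lat", "lon"),
            coords={"member": np.arange(n_members), **coords},
            attrs={"units": "g CH4 cell-1 step-1"},
        )
    ds.attrs["n_members"] = n_members
    return ds


# ---------------------------------------------------------------------------
# regional aggregation
# ---------------------------------------------------------------------------

def to_regional_annual(field: xr.Dataset, regions: dict | None = None) -> pd.DataFrame:
    """Annual regional emission totals in Tg CH4 yr-1.

    Returns a tidy frame (region, year, tg, tg_sd); tg_sd is the
    across-member s.d. when member fields are present, else NaN. The region
    masks partition the domain, so regional totals sum to 'BA' exactly.
    """
    masks = region_masks(field["lat"].values, field["lon"].values, regions)
    years = pd.DatetimeIndex(field["time"].values).year
    em = field["emission"].values  # (time, lat, lon), grams
    members = field["member_emission"].values if "member_emission" in field else None
    rows = []
    for region, mask in masks.items():
        cell_sum = em[:, mask].sum(axis=1)  # g per step
        by_year = pd.Series(cell_sum).groupby(years).sum() * TG_PER_G
        if members is not None:
            msum = members[:, :, mask].sum(axis=2)  # (member, time)
            myear = np.stack(
                [pd.Series(msum[m]).groupby(years).sum().values for m in range(msum.shape[0])]
            ) * TG_PER_G
            sd = myear.std(axis=0, ddof=1) if msum.shape[0] > 1 else np.full(by_year.size, np.nan)
        else:
            sd = np.full(by_year.size, np.nan)
        for y, v, s in zip(by_year.index, by_year.values, sd):
            rows.append({"region": region, "year": int(y), "tg": float(v), "tg_sd": float(s)})
    return pd.DataFrame(rows)


def monthly_regional_series(field: xr.Dataset, region_mask: np.ndarray) -> pd.DataFrame:
    """Monthly emission totals (Tg) for one region: rows = year, cols = month 1..12."""
    idx = pd.DatetimeIndex(field["time"].values)
    em = field["emission"].values[:, region_mask].sum(axis=1) * TG_PER_G
    df = pd.DataFrame({"year": idx.year, "month": idx.month, "tg": em})
    out = df.pivot_table(index="year", columns="month", values="tg", aggfunc="sum", fill_value=0.0)
    return out.reindex(columns=range(1, 13), fill_value=0.0)


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    """OLS linear trend of an annual series with a two-sided t test."""

    slope: float  # units per year
    intercept: float  # fitted value at the first year
    p_value: float
    percent_change: float  # 100 * slope * (n_years - 1) / fitted(first year)
    n_years: int


def linear_trend(annual, years=None) -> TrendResult:
    """Fit an OLS trend to an annual series.

    ``annual`` may be a pandas Series (index = year) or an array; a constant
    series reports slope 0 with p = 1 (zero t statistic).
    """
    if isinstance(annual, pd.Series):
        years = annual.index.values if years is None else years
        y = annual.values.astype(float)
    else:
        y = np.asarray(annual, dtype=float)
    n = y.size
    if n < 3:
        raise InvalidConfigError("trend needs >= 3 years")
    t = np.arange(n, dtype=float) if years is None else np.asarray(years, dtype=float)
    t = t - t[0]
    res = stats.linregress(t, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (intercept + slope * t)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, np.abs(y).max())) and abs(slope) <= 1e-15 * max(1.0, np.abs(y).max()):
        p = 1.0
    elif np.isnan(res.pvalue):
        p = 1.0 if slope == 0 else 0.0
    else:
        p = float(res.pvalue)
    first = intercept
    pct = 100.0 * slope * (n - 1) / first if abs(first) > 1e-300 else np.nan
    return TrendResult(slope=slope, intercept=intercept, p_value=p,
                       percent_change=pct, n_years=n)


def seasonal_trend_split(monthly: pd.DataFrame) -> pd.Series:
    """Share of the annual trend carried by each calendar month.

    ``monthly`` is a year x month frame (as from
    :func:`monthly_regional_series`). Each month's annual series gets its
    own OLS slope; fractions are slopes divided by the slope of the annual
    (row-sum) series, so they sum to 1 exactly by OLS linearity.
    """
    years = monthly.index.values.astype(float)
    t = years - years[0]
    slopes = {}
    for m in monthly.columns:
        slopes[m] = float(stats.linregress(t, monthly[m].values.astype(float)).slope)
    total = float(stats.linregress(t, monthly.sum(axis=1).values.astype(float)).slope)
    if abs(total) < 1e-300:
        raise InvalidConfigError("annual trend is zero; monthly shares undefined")
    return pd.Series({m: s / total for m, s in slopes.items()}, name="trend_fraction")
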