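"""Synthetic scene generator: drivers, wetland maps, truth fluxes, site records.

The generator emulates the statistical structure the upscaling analysis
assumes, so every downstream stage can be verified against a known truth
without external data products:

* weekly driver fields = latitude-dependent climatological seasonal cycle
  + AR(1) anomalies + linear decadal trends (warming / greening);
* gross primary productivity (GPP) anomalies positively coupled to air
  temperature (TA) anomalies, soil water content (SWC) coupled to recent
  precipitation (P);
* a known methane flux law per wetland type (bog / fen / marsh / tundra)
  with lagged soil-temperature and GPP dependence — the intra-seasonal
  hysteresis the upscaling model is built to capture;
* eddy-covariance sites reporting noisy weekly fluxes over a site window and
  chamber sites reporting a single noisy period mean.

Seasonal cycles are pure functions of the step-start calendar date, so a
trend-free noise-free scene repeats exactly wherever step dates share a day
of year, and calendar-month statistics carry no spurious drift.

Everything is a pure function of (grid, config, seed): one master seed fans
out to per-component child seeds via :class:`numpy.random.SeedSequence`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .errors import AlignmentError, CapacityError, InvalidConfigError
from .grids import DRIVER_UNITS, DRIVERS, GridSpec, STEP_DAYS, WETLAND_TYPES

WEEKS_PER_CYCLE = 52

FLUX_UNITS = "nmol CH4 m-2 s-1"


@dataclass(frozen=True)
class TypeResponse:
    """Flux-law parameters for one wetland type.

    intensity(t) = baseline * q10_like**((TS(t - lag_ts) - t_ref)/10)
                   * (1 + gpp_coefficient * GPP(t - lag_gpp)) + noise,
    truncated at zero.
    """

    baseline: float  # nmol CH4 m-2 s-1 at TS = t_ref and GPP = 0
    q10_like: float  # dimensionless temperature sensitivity
    gpp_coefficient: float  # per (g C m-2 d-1)
    lag_ts: int  # weeks
    lag_gpp: int  # weeks
    noise_sd: float  # nmol CH4 m-2 s-1, process noise


#: default per-type responses; magnitudes follow the field's rule of thumb
#: fen/marsh > bog > tundra, Q10-like sensitivities 2-3, lags of 0-3 weeks.
DEFAULT_RESPONSES = {
    "bog": TypeResponse(20.0, 2.5, 0.15, 1, 2, 4.0),
    "fen": TypeResponse(45.0, 2.2, 0.12, 0, 2, 6.0),
    "marsh": TypeResponse(60.0, 2.8, 0.10, 0, 1, 8.0),
    "tundra": TypeResponse(12.0, 3.0, 0.18, 2, 3, 3.0),
}


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the synthetic truth.

    ``noise_scale`` multiplies every stochastic term (driver AR(1)
    innovations, flux process noise, observation noise); 0 gives a fully
    deterministic seasonal-only scene. Trends are per year; temperatures in
    degC, GPP in g C m-2 d-1.
    """

    responses: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSES))
    t_ref: float = 10.0  # degC reference for the Q10-like response
    max_lag: int = 8  # weeks; planted lags must stay <= this
    # linear driver trends, units per year
    trend: dict = field(
        default_factory=lambda: {
            "TS": 0.06, "TA": 0.08, "GPP": 0.02,
            "PA": 0.0, "P": 0.0, "WS": 0.0, "SC": 0.0, "SWC": 0.0,
        }
    )
    #: optional per-driver month restriction of the trend, e.g. {"TA": (6, 7)}
    #: applies that driver's trend only to steps starting in those months
    trend_months: dict = field(default_factory=dict)
    ar1: float = 0.6  # weekly AR(1) coefficient of driver anomalies
    # weekly innovation standard deviations per driver
    innovation_sd: dict = field(
        default_factory=lambda: {
            "TS": 0.8, "TA": 1.5, "GPP": 0.35,
            "PA": 0.4, "P": 4.0, "WS": 0.4, "SC": 0.05, "SWC": 0.015,
        }
    )
    couple_gpp_ta: float = 0.5  # share of GPP innovation drawn from TA's
    couple_swc_p: float = 0.5  # share of SWC innovation drawn from P's
    noise_scale: float = 1.0
    ec_noise_sd: float = 8.0  # nmol CH4 m-2 s-1 on weekly EC observations
    chamber_noise_sd: float = 6.0  # nmol CH4 m-2 s-1 on chamber period means
    chamber_start_month: int = 6
    chamber_end_month: int = 9
    wetland_cover: float = 0.7  # fraction of cells that are wetland
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.responses.items():
            if r.lag_ts < 0 or r.lag_gpp < 0:
                raise InvalidConfigError(f"{name}: lags must be >= 0")
            if max(r.lag_ts, r.lag_gpp) > self.max_lag:
                raise InvalidConfigError(f"{name}: planted lag exceeds max_lag")
            if r.noise_sd < 0:
                raise InvalidConfigError(f"{name}: noise_sd must be >= 0")
        if self.noise_scale < 0:
            raise InvalidConfigError("noise_scale must be >= 0")
        if not 0.0 <= self.wetland_cover <= 1.0:
            raise InvalidConfigError("wetland_cover must be in [0, 1]")

    def child_seed(self, stream: int) -> np.random.SeedSequence:
        """Deterministic per-component seed stream from the master seed."""
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))


def with_noise(cfg: TruthConfig, scale: float) -> TruthConfig:
    """Copy of ``cfg`` with a different global noise scale."""
    return replace(cfg, noise_scale=scale)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _day_of_year(times: np.ndarray) -> np.ndarray:
    """Fractional day-of-year (0-based) of each step-start date."""
    idx = pd.DatetimeIndex(times)
    return idx.dayofyear.values.astype(float) - 1.0


def _seasonal_cycles(grid: GridSpec) -> dict:
    """Climatological weekly cycles per driver, shape (time, lat).

    Cycles are pure functions of the step-start calendar date (day of year),
    so calendar-month statistics are stationary when trends and noise are
    off, and two grids sharing step dates produce identical cycles.
    """
    doy = _day_of_year(grid.times)[:, None]  # (t, 1)
    ph = doy / 365.25
    lat = grid.lats[None, :]  # (1, lat)
    # winter minimum at phase 0 (early January)
    s = -np.cos(2 * np.pi * ph)  # -1 in winter, +1 midsummer
    lat_off = -(lat - lat.mean())  # colder poleward
    ta = -4.0 + 0.8 * lat_off + 14.0 * s
    ts = 2.0 + 0.5 * lat_off + 9.0 * np.broadcast_to(
        -np.cos(2 * np.pi * (doy - 14.0) / 365.25), ta.shape
    )  # soil lags air by ~2 weeks, damped
    gpp = 6.0 * np.exp(-0.5 * ((doy / 7.0 - 26.0) / 6.0) ** 2)
    gpp = np.broadcast_to(gpp, ta.shape)
    pa = 95.0 + 1.0 * np.cos(2 * np.pi * ph) + 0.0 * lat
    p = 10.0 + 5.0 * s + 0.0 * lat
    ws = 3.5 + 0.6 * np.cos(2 * np.pi * ph) + 0.0 * lat
    sc = 1.0 / (1.0 + np.exp(ta / 2.0))  # snow follows the air-temperature cycle
    swc = 0.35 + 0.05 * s + 0.0 * lat
    return {"TS": ts, "TA": ta, "GPP": gpp, "PA": pa, "P": p, "WS": ws, "SC": sc, "SWC": swc}


def _ar1(innov: np.ndarray, phi: float) -> np.ndarray:
    """AR(1) recursion along axis 0 with stationary-variance initial state."""
    out = np.empty_like(innov)
    out[0] = innov[0] / np.sqrt(max(1.0 - phi**2, 1e-12))
    for t in range(1, innov.shape[0]):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def generate_drivers(grid: GridSpec, cfg: TruthConfig) -> xr.Dataset:
    """Generate all 8 weekly driver fields on ``grid``.

    Each driver = seasonal cycle + AR(1) anomaly + linear trend. GPP
    anomalies are positively coupled to TA anomalies and SWC to recent P via
    shared innovations; GPP, P, WS are truncated at 0 and SC, SWC clipped to
    their physical ranges.
    """
    rng = np.random.default_rng(cfg.child_seed(0))
    nt, nla, nlo = grid.times.size, grid.lats.size, grid.lons.size
    cyc = _seasonal_cycles(grid)
    years = (grid.times - grid.times[grid.spinup_weeks]) / np.timedelta64(1, "D") / 365.25
    years = years.astype(float)[:, None, None]

    # innovations drawn in fixed driver order for determinism
    innov = {
        d: cfg.noise_scale * cfg.innovation_sd[d] * rng.standard_normal((nt, nla, nlo))
        for d in DRIVERS
    }
    # positive couplings: share innovations before the AR recursion
    a = cfg.couple_gpp_ta
    innov["GPP"] = (
        a * cfg.innovation_sd["GPP"] / cfg.innovation_sd["TA"] * innov["TA"]
        + np.sqrt(1 - a**2) * innov["GPP"]
    )
    b = cfg.couple_swc_p
    innov["SWC"] = (
        b * cfg.innovation_sd["SWC"] / cfg.innovation_sd["P"] * innov["P"]
        + np.sqrt(1 - b**2) * innov["SWC"]
    )

    months = pd.DatetimeIndex(grid.times).month.values
    data = {}
    for d in DRIVERS:
        anom = _ar1(innov[d], cfg.ar1)
        trend_term = cfg.trend.get(d, 0.0) * years
        if d in cfg.trend_months:
            sel = np.isin(months, list(cfg.trend_months[d])).astype(float)
            trend_term = trend_term * sel[:, None, None]
        vals = cyc[d][:, :, None] + anom + trend_term
        if d in ("GPP", "P", "WS"):
            vals = np.maximum(vals, 0.0)
        elif d == "SC":
            vals = np.clip(vals, 0.0, 1.0)
        elif d == "SWC":
            vals = np.clip(vals, 0.01, 0.99)
        data[d] = xr.DataArray(
            vals,
            dims=("time", "lat", "lon"),
            coords={"time": grid.times, "lat": grid.lats, "lon": grid.lons},
            attrs={"units": DRIVER_UNITS[d]},
        )
    ds = xr.Dataset(data)
    ds.attrs["spinup_weeks"] = grid.spinup_weeks
    return ds


# ---------------------------------------------------------------------------
# wetlands
# ---------------------------------------------------------------------------

def generate_wetlands(grid: GridSpec, cfg: TruthConfig) -> xr.Dataset:
    """Static wetland-fraction map plus per-type fraction layers.

    ``wetland_frac`` is the cell fraction occupied by wetland (0 for
    non-wetland cells); ``type_frac`` partitions the wetland portion among
    bog/fen/marsh/tundra and sums to 1 over types wherever wetland_frac > 0.
    Tundra share increases poleward.
    """
    rng = np.random.default_rng(cfg.child_seed(1))
    nla, nlo = grid.lats.size, grid.lons.size
    smooth = ndimage.gaussian_filter(rng.standard_normal((nla, nlo)), sigma=1.5)
    order = np.argsort(smooth.ravel())
    thresh = smooth.ravel()[order[int((1 - cfg.wetland_cover) * smooth.size)]]
    wet = smooth >= thresh
    frac = np.where(wet, np.clip(0.25 + 0.15 * smooth, 0.02, 0.9), 0.0)

    lat_w = (grid.lats - grid.lats.min()) / max(np.ptp(grid.lats), 1e-9)  # 0 south .. 1 north
    base = np.stack(
        [
            1.0 + 0.0 * lat_w,          # bog
            1.2 - 0.4 * lat_w,          # fen: more southerly
            0.6 - 0.3 * lat_w,          # marsh
            0.3 + 1.5 * lat_w,          # tundra: poleward
        ]
    )  # (type, lat)
    noise = 0.25 * ndimage.gaussian_filter(
        rng.standard_normal((len(WETLAND_TYPES), nla, nlo)), sigma=(0, 1.5, 1.5)
    )
    w = np.maximum(base[:, :, None] + noise, 0.02)
    tf = w / w.sum(axis=0, keepdims=True)
    tf = np.where(wet[None, :, :], tf, 0.0)

    ds = xr.Dataset(
        {
            "wetland_frac": xr.DataArray(
                frac, dims=("lat", "lon"),
                coords={"lat": grid.lats, "lon": grid.lons},
                attrs={"units": "fraction"},
            ),
            "type_frac": xr.DataArray(
                tf, dims=("wetland_type", "lat", "lon"),
                coords={"wetland_type": list(WETLAND_TYPES), "lat": grid.lats, "lon": grid.lons},
                attrs={"units": "fraction"},
            ),
        }
    )
    return ds


# ---------------------------------------------------------------------------
# truth flux
# ---------------------------------------------------------------------------

def _check_same_grid(a: xr.Dataset, b: xr.Dataset) -> None:
    for dim in ("lat", "lon"):
        if a[dim].size != b[dim].size or not np.allclose(a[dim].values, b[dim].values):
            raise AlignmentError(f"{dim} axes differ between gridded inputs")


def type_intensity(drivers: xr.Dataset, cfg: TruthConfig, spinup: int | None = None,
                   rng: np.random.Generator | None = None) -> xr.DataArray:
    """Noise-free-or-noisy per-type flux intensity over the analysis window.

    Applies the lagged flux law to the driver cube; the first ``spinup``
    steps of the cube serve as lag history and are excluded from the output.
    """
    spinup = int(drivers.attrs.get("spinup_weeks", 0)) if spinup is None else spinup
    need = max(max(r.lag_ts, r.lag_gpp) for r in cfg.responses.values())
    if spinup < need:
        raise AlignmentError(
            f"driver cube has {spinup} spin-up weeks but the flux law needs {need}"
        )
    ts = drivers["TS"].values
    gpp = drivers["GPP"].values
    nt = ts.shape[0] - spinup
    out = np.empty((len(WETLAND_TYPES), nt) + ts.shape[1:])
    for k, wt in enumerate(WETLAND_TYPES):
        r = cfg.responses[wt]
        sl_ts = slice(spinup - r.lag_ts, ts.shape[0] - r.lag_ts)
        sl_gpp = slice(spinup - r.lag_gpp, ts.shape[0] - r.lag_gpp)
        mean = (
            r.baseline
            * r.q10_like ** ((ts[sl_ts] - cfg.t_ref) / 10.0)
            * (1.0 + r.gpp_coefficient * gpp[sl_gpp])
        )
        if rng is not None and cfg.noise_scale * r.noise_sd > 0:
            mean = mean + cfg.noise_scale * r.noise_sd * rng.standard_normal(mean.shape)
        out[k] = np.maximum(mean, 0.0)
    return xr.DataArray(
        out,
        dims=("wetland_type", "time", "lat", "lon"),
        coords={
            "wetland_type": list(WETLAND_TYPES),
            "time": drivers["time"].values[spinup:],
            "lat": drivers["lat"].values,
            "lon": drivers["lon"].values,
        },
        attrs={"units": FLUX_UNITS},
    )


def generate_truth_flux(drivers: xr.Dataset, wetlands: xr.Dataset, cfg: TruthConfig) -> xr.Dataset:
    """Ground-truth flux field: per-type intensity and per-cell emission.

    Emission (g CH4 per cell per weekly step) is computed by
    :func:`wetch4.upscaling.emission_from_intensity`; zero-wetland cells get
    exactly zero emission regardless of intensity.
    """
    from .upscaling import emission_from_intensity  # local import, avoids cycle

    _check_same_grid(drivers, wetlands)
    rng = np.random.default_rng(cfg.child_seed(2))
    inten = type_intensity(drivers, cfg, rng=rng)
    ds = xr.Dataset({"intensity": inten})
    ds["emission"] = emission_from_intensity(inten, wetlands)
    return ds


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

@dataclass
class SiteRecord:
    """One observation site.

    ``frequency`` is 'weekly' (eddy covariance: a weekly flux series over the
    window) or 'period_mean' (chamber: one mean flux over the window).
    """

    site_id: str
    wetland_type: str
    lat: float
    lon: float
    frequency: str  # 'weekly' | 'period_mean'
    start: np.datetime64
    end: np.datetime64  # exclusive
    flux: np.ndarray | float  # weekly series, or a single mean

    def __post_init__(self) -> None:
        if self.frequency not in ("weekly", "period_mean"):
            raise InvalidConfigError(f"bad frequency {self.frequency!r}")
        if self.frequency == "period_mean" and np.ndim(self.flux) != 0:
            raise InvalidConfigError("period_mean records carry exactly one value")


def sample_sites(
    truth: xr.Dataset,
    wetlands: xr.Dataset,
    n_ec: int,
    n_chamber: int,
    cfg: TruthConfig,
) -> list[SiteRecord]:
    """Draw EC and chamber sites from wetland cells of the truth field.

    Each site lands in a distinct wetland cell; its wetland type is drawn
    with probability proportional to the cell's type fractions. EC sites
    observe 1-3 years of noisy weekly intensity; chamber sites report one
    noisy mean over a ``chamber_start_month``..``chamber_end_month`` window
    of a random year.
    """
    if n_ec + n_chamber < 1:
        raise InvalidConfigError("need at least one site")
    rng = np.random.default_rng(cfg.child_seed(3))
    frac = wetlands["wetland_frac"].values
    wet_idx = np.argwhere(frac > 0)
    if n_ec + n_chamber > len(wet_idx):
        raise CapacityError(
            f"requested {n_ec + n_chamber} sites but only {len(wet_idx)} wetland cells"
        )
    pick = rng.choice(len(wet_idx), size=n_ec + n_chamber, replace=False)
    times = truth["time"].values
    lats = truth["lat"].values
    lons = truth["lon"].values
    tf = wetlands["type_frac"].values
    noise = cfg.noise_scale
    records: list[SiteRecord] = []
    for s, cell in enumerate(pick):
        i, j = wet_idx[cell]
        wt_k = rng.choice(len(WETLAND_TYPES), p=tf[:, i, j])
        wt = WETLAND_TYPES[wt_k]
        series = truth["intensity"].values[wt_k, :, i, j]
        is_ec = s < n_ec
        if is_ec:
            n_weeks = int(rng.integers(52, 157))
            n_weeks = min(n_weeks, times.size)
            t0 = int(rng.integers(0, times.size - n_weeks + 1))
            obs = series[t0 : t0 + n_weeks] + noise * cfg.ec_noise_sd * rng.standard_normal(n_weeks)
            records.append(
                SiteRecord(
                    site_id=f"EC{s:03d}", wetland_type=wt,
                    lat=float(lats[i]), lon=float(lons[j]), frequency="weekly",
                    start=times[t0], end=times[t0 + n_weeks - 1] + np.timedelta64(STEP_DAYS, "D"),
                    flux=obs,
                )
            )
        else:
            yrs = pd.DatetimeIndex(times).year
            year = int(rng.choice(np.unique(yrs)))
            months = pd.DatetimeIndex(times).month
            sel = (yrs == year) & (months >= cfg.chamber_start_month) & (months <= cfg.chamber_end_month)
            if not sel.any():  # window empty for this year: fall back to whole year
                sel = yrs == year
            mean = float(series[sel].mean()) + noise * cfg.chamber_noise_sd * float(rng.standard_normal())
            t_sel = times[sel]
            records.append(
                SiteRecord(
                    site_id=f"CH{s:03d}", wetland_type=wt,
                    lat=float(lats[i]), lon=float(lons[j]), frequency="period_mean",
                    start=t_sel[0], end=t_sel[-1] + np.timedelta64(STEP_DAYS, "D"),
                    flux=mean,
                )
            )
    return records


# ---------------------------------------------------------------------------
# purpose-built scenes for calibration / recovery studies
# ---------------------------------------------------------------------------

def ar1_panel(n: int, n_series: int, phi: float = 0.6, sd: float = 1.0,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Independent AR(1) series, shape (n, n_series); null-scene building block."""
    rng = np.random.default_rng() if rng is None else rng
    innov = sd * rng.standard_normal((n, n_series))
    return _ar1(innov, phi)


def planted_dominance_scene(
    n_cells: int = 200,
    n_years: int = 20,
    frac_ts: float = 0.5,
    effect: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Annual anomaly scene with a known dominant driver per cell.

    Returns ``(flux, drivers, truth_winner)`` where ``flux`` is
    (n_cells, n_years), ``drivers`` maps driver name -> (n_cells, n_years)
    independent standard-normal annual anomalies, and cell c's flux is
    ``effect`` times its planted driver's anomaly plus noise. With
    ``effect=0`` the scene is null (flux independent of all drivers).
    """
    rng = np.random.default_rng(seed)
    drivers = {d: rng.standard_normal((n_cells, n_years)) for d in DRIVERS}
    n_ts = int(round(frac_ts * n_cells))
    truth = np.array(["TS"] * n_ts + ["GPP"] * (n_cells - n_ts))
    flux = noise_sd * rng.standard_normal((n_cells, n_years))
    if effect != 0.0:
        for c in range(n_cells):
            flux[c] += effect * drivers[truth[c]][c]
    return flux, drivers, truth
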