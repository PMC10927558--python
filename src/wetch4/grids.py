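"""Grid geometry: the 0.5-degree / 7-day working grid and spherical cell areas.

All gridded objects in the package live on a regular lat/lon grid with cell
centres at half-resolution offsets and a strictly uniform weekly time axis.
The time axis optionally carries a spin-up period of ``spinup_weeks`` steps
before the analysis window so that lagged features are defined from the very
first analysed week.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError

EARTH_RADIUS_KM = 6371.0

#: canonical driver short names, fixed ordering used everywhere
DRIVERS = ("TS", "TA", "GPP", "PA", "P", "WS", "SC", "SWC")

DRIVER_UNITS = {
    "TS": "degC",
    "TA": "degC",
    "GPP": "g C m-2 d-1",
    "PA": "kPa",
    "P": "mm wk-1",
    "WS": "m s-1",
    "SC": "fraction",
    "SWC": "m3 m-3",
}

WETLAND_TYPES = ("bog", "fen", "marsh", "tundra")

STEP_DAYS = 7


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with a uniform weekly time axis.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Domain edges in degrees. Cell centres sit at half-resolution offsets.
    resolution : float
        Cell size in degrees (default 0.5).
    time_start, time_end : str
        ISO dates bounding the analysis window ``[time_start, time_end)``.
    spinup_weeks : int
        Extra weekly steps generated before ``time_start`` so lagged
        features are defined for the whole analysis window.
    """

    lat_min: float = 60.0
    lat_max: float = 65.0
    lon_min: float = 60.0
    lon_max: float = 70.0
    resolution: float = 0.5
    time_start: str = "2002-01-01"
    time_end: str = "2022-01-01"
    spinup_weeks: int = 8

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvalidConfigError("grid resolution must be > 0")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise InvalidConfigError("grid extent must be positive in both axes")
        if self.spinup_weeks < 0:
            raise InvalidConfigError("spinup_weeks must be >= 0")
        if np.datetime64(self.time_end) <= np.datetime64(self.time_start):
            raise InvalidConfigError("time_end must be after time_start")

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution))
        return self.lat_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution))
        return self.lon_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def n_steps(self) -> int:
        """Number of weekly steps in the analysis window (spin-up excluded)."""
        span = (np.datetime64(self.time_end) - np.datetime64(self.time_start)) / np.timedelta64(1, "D")
        return int(np.ceil(span / STEP_DAYS))

    @property
    def times(self) -> np.ndarray:
        """Full weekly step-start dates, spin-up included."""
        start = np.datetime64(self.time_start) - np.timedelta64(self.spinup_weeks * STEP_DAYS, "D")
        return start + np.timedelta64(STEP_DAYS, "D") * np.arange(self.spinup_weeks + self.n_steps)

    @property
    def analysis_times(self) -> np.ndarray:
        return self.times[self.spinup_weeks:]

    def cell_areas_km2(self) -> np.ndarray:
        """Per-latitude-row spherical cell areas (km^2), shape (n_lat,)."""
        return cell_area(self.lats, self.resolution)


def cell_area(lat_center, resolution: float) -> np.ndarray:
    """Spherical area of a ``resolution`` x ``resolution`` degree cell, km^2.

    Uses R^2 * dlambda * (sin(phi2) - sin(phi1)) with R = 6371 km, where
    phi1/phi2 are the cell's southern/northern edges.
    """
    lat_center = np.asarray(lat_center, dtype=float)
    half = resolution / 2.0
    phi1 = np.radians(np.clip(lat_center - half, -90.0, 90.0))
    phi2 = np.radians(np.clip(lat_center + half, -90.0, 90.0))
    dlam = np.radians(resolution)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))


@dataclass(frozen=True)
class RegionBox:
    """Inclusive lat/lon box used for regional aggregation."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def mask(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        """Boolean (n_lat, n_lon) mask of cell centres inside the box."""
        la = (lats >= self.lat_min) & (lats <= self.lat_max)
        lo = (lons >= self.lon_min) & (lons <= self.lon_max)
        return la[:, None] & lo[None, :]


#: hotspot boxes: Western Siberian lowlands and Hudson Bay lowlands
DEFAULT_REGIONS = {
    "WSL": RegionBox(52.0, 74.0, 60.0, 94.5),
    "HBL": RegionBox(50.0, 60.0, -96.0, -75.0),
}


def region_masks(lats: np.ndarray, lons: np.ndarray, regions=None) -> dict:
    """Masks for the whole domain ('BA'), each hotspot box, and 'non-hotspot'.

    The returned masks partition the domain: BA = union of hotspots and
    non-hotspot, with hotspot overlap (none for the defaults) assigned to the
    first region in iteration order.
    """
    regions = DEFAULT_REGIONS if regions is None else regions
    masks = {"BA": np.ones((lats.size, lons.size), dtype=bool)}
    claimed = np.zeros((lats.size, lons.size), dtype=bool)
    for name, box in regions.items():
        m = box.mask(lats, lons) & ~claimed
        masks[name] = m
        claimed |= m
    masks["non-hotspot"] = ~claimed
    return masks
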