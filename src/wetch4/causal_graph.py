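"""Lagged causal discovery for flux drivers: partial correlation and PCMCI.

The scientific question is which of the eight environmental drivers (TS,
TA, GPP, PA, P, WS, SC, SWC) are *causal* parents of the weekly methane flux
of a wetland type, and at which weekly lag, after conditioning away the
confounding influence of the other drivers. The machinery is the two-stage
PCMCI scheme:

1. **PC condition selection** — iteratively discard candidate (driver, lag)
   pairs that are conditionally independent of the target given growing
   subsets of the currently strongest other candidates;
2. **MCI tests** — for each surviving candidate ``X`` at lag ``tau``, test
   the momentary conditional independence of ``X(t-tau)`` and ``flux(t)``
   given both the flux's other candidate parents and the parents of ``X``
   (shifted by ``tau``), and keep links with p <= alpha.

The conditional-independence test throughout is linear partial correlation
with a two-sided t test; the same primitive is reused by the attribution
module. Multi-site panels pool lagged samples across sites; lags never span
a site boundary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, InvalidConfigError
from .grids import DRIVERS

TARGET = "flux"


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def partial_correlation(x, y, conditioning=(), dof_loss: int = 0) -> tuple[float, float]:
    """Linear partial correlation of ``x`` and ``y`` given ``conditioning``.

    Both series are least-squares projected on the conditioning set plus an
    intercept; rho is the Pearson correlation of the residuals and the
    two-sided p-value comes from the t distribution with
    ``n - |conditioning| - 2 - dof_loss`` degrees of freedom. With an empty
    conditioning set this is the plain Pearson correlation. ``dof_loss``
    accounts for parameters removed from the series before the call (one
    per pre-removed regressor, e.g. 1 for detrended inputs).

    Raises
    ------
    DegenerateInputError
        If either residual series is (numerically) constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cond = [np.asarray(c, dtype=float) for c in conditioning]
    n = x.size
    k = len(cond)
    if y.size != n or any(c.size != n for c in cond):
        raise InvalidConfigError("all series must have equal length")
    if n <= k + 2:
        raise InsufficientDataError(f"n={n} too small for {k} conditioning series")
    if cond:
        Z = np.column_stack([np.ones(n)] + cond)
        coef_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rx = x - Z @ coef_x
        ry = y - Z @ coef_y
    else:
        rx = x - x.mean()
        ry = y - y.mean()
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    if sx <= 1e-13 * np.sqrt(n) * max(np.abs(x).max(), 1.0) or \
       sy <= 1e-13 * np.sqrt(n) * max(np.abs(y).max(), 1.0):
        raise DegenerateInputError("constant residuals in partial correlation")
    rho = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - k - 2 - dof_loss
    if dof < 1:
        raise InsufficientDataError(f"no residual degrees of freedom (n={n}, k={k})")
    if 1.0 - rho**2 < 1e-15:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return rho, p


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesPanel:
    """Aligned weekly series of flux + drivers for sites of one wetland type.

    ``frames`` maps site_id -> DataFrame indexed by time with a ``flux``
    column and one column per driver. Lagged samples are built per site and
    concatenated, so lags never cross site boundaries.
    """

    frames: dict
    wetland_type: str = ""
    variables: tuple = DRIVERS

    def __post_init__(self) -> None:
        for sid, df in self.frames.items():
            missing = {TARGET, *self.variables} - set(df.columns)
            if missing:
                raise InvalidConfigError(f"site {sid}: missing columns {sorted(missing)}")
            if df.isna().any().any():
                raise InvalidConfigError(f"site {sid}: NaNs in panel")

    def min_length(self) -> int:
        return min(len(df) for df in self.frames.values())

    def check_lag(self, max_lag: int) -> None:
        if max_lag < 0:
            raise InvalidConfigError("max_lag must be >= 0")
        if self.min_length() < max_lag + 10:
            raise InsufficientDataError(
                f"shortest site series ({self.min_length()} wk) < max_lag + 10"
            )

    def lagged(self, pairs, target: str, start: int):
        """Pooled lagged samples.

        For each site, rows t = start .. n-1 yield target(t) and one column
        per (var, lag) pair holding var(t - lag). Returns (y, X) with X of
        shape (n_samples, len(pairs)).
        """
        ys, Xs = [], []
        for sid in sorted(self.frames):
            df = self.frames[sid]
            n = len(df)
            if n <= start:
                continue
            idx = np.arange(start, n)
            ys.append(df[target].values[idx])
            cols = [df[v].values[idx - lag] for v, lag in pairs]
            Xs.append(np.column_stack(cols) if cols else np.empty((idx.size, 0)))
        if not ys:
            raise InsufficientDataError("no usable samples at this lag depth")
        return np.concatenate(ys), np.vstack(Xs)


def build_panel(records, drivers: "xr.Dataset", wetland_type: str) -> TimeSeriesPanel:
    """Panel from weekly site records plus the driver cube at each site cell."""
    import xarray as xr  # noqa: F401  (type only)

    frames = {}
    times = pd.DatetimeIndex(drivers["time"].values)
    for rec in records:
        if rec.wetland_type != wetland_type or rec.frequency != "weekly":
            continue
        i = int(np.argmin(np.abs(drivers["lat"].values - rec.lat)))
        j = int(np.argmin(np.abs(drivers["lon"].values - rec.lon)))
        sel = (times >= rec.start) & (times < rec.end)
        df = pd.DataFrame(
            {d: drivers[d].values[sel, i, j] for d in DRIVERS},
            index=times[sel],
        )
        df[TARGET] = np.asarray(rec.flux, dtype=float)
        frames[rec.site_id] = df
    return TimeSeriesPanel(frames=frames, wetland_type=wetland_type)


# ---------------------------------------------------------------------------
# PCMCI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Link:
    driver: str
    lag: int
    strength: float  # MCI partial correlation, in [-1, 1]
    p_value: float


@dataclass
class CausalGraph:
    """Retained (driver, lag) parents of the flux for one wetland type."""

    links: list = field(default_factory=list)
    alpha: float = 0.05
    max_lag: int = 8
    wetland_type: str = ""

    def pairs(self) -> list[tuple[str, int]]:
        return [(l.driver, l.lag) for l in self.links]

    def to_dict(self) -> dict:
        return {
            "wetland_type": self.wetland_type,
            "alpha": self.alpha,
            "max_lag": self.max_lag,
            "links": [
                {"driver": l.driver, "lag": l.lag, "strength": l.strength, "p_value": l.p_value}
                for l in self.links
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CausalGraph":
        return cls(
            links=[Link(x["driver"], int(x["lag"]), float(x["strength"]), float(x["p_value"]))
                   for x in d["links"]],
            alpha=float(d["alpha"]),
            max_lag=int(d["max_lag"]),
            wetland_type=d.get("wetland_type", ""),
        )


def _sort_key(cand, strength):
    # descending |rho|, ties by (driver name, lag)
    return (-abs(strength[cand]), cand[0], cand[1])


def pc_parent_selection(
    panel: TimeSeriesPanel,
    max_lag: int,
    alpha: float = 0.05,
    target: str = TARGET,
    min_lag: int = 0,
    cond_cap: int = 3,
) -> list[tuple[str, int]]:
    """PC-style condition selection of candidate parents of ``target``.

    Candidates are every (driver, lag) with lag in ``min_lag..max_lag``
    (``min_lag=1`` when selecting parents of a driver, so a variable's own
    past may enter but no contemporaneous loop does). A candidate is removed
    as soon as it tests independent of the target (p > alpha) given the
    ``p``-strongest other surviving candidates, for condition sizes
    p = 0, 1, ... up to ``cond_cap``. Ordering is deterministic: descending
    |partial correlation| with (driver, lag) tie-break.
    """
    panel.check_lag(max_lag)
    if max_lag > panel.min_length() / 5:
        raise InsufficientDataError("max_lag too large for panel length")
    cands = [(d, lag) for d in panel.variables for lag in range(min_lag, max_lag + 1)
             if not (d == target and lag == 0)]
    start = max_lag  # common sample window for comparability across tests

    strength: dict = {}
    keep = []
    y, X = panel.lagged(cands, target, start)
    for idx, c in enumerate(cands):
        try:
            rho, p = partial_correlation(X[:, idx], y)
        except DegenerateInputError:
            continue  # constant candidate column carries no information
        if p <= alpha:
            strength[c] = rho
            keep.append(c)

    size = 1
    while size <= cond_cap and len(keep) > size:
        order = sorted(keep, key=lambda c: _sort_key(c, strength))
        y, X = panel.lagged(order, target, start)
        col = {c: X[:, i] for i, c in enumerate(order)}
        new_keep = []
        for c in order:
            others = [o for o in order if o != c][:size]
            try:
                rho, p = partial_correlation(col[c], y, [col[o] for o in others])
            except DegenerateInputError:
                continue
            if p <= alpha:
                strength[c] = rho
                new_keep.append(c)
        if not new_keep:
            keep = []
            break
        keep = new_keep
        size += 1
    return sorted(keep, key=lambda c: _sort_key(c, strength))


def mci_tests(
    panel: TimeSeriesPanel,
    candidates,
    max_lag: int,
    alpha: float = 0.05,
    cond_cap: int = 3,
    driver_parents: dict | None = None,
    wetland_type: str = "",
) -> CausalGraph:
    """Momentary-conditional-independence tests over candidate flux parents.

    For candidate (X, tau) the conditioning set is the flux's other candidate
    parents at their lags plus the PC-selected parents of X, each shifted by
    tau. Links with p <= alpha are retained with the MCI partial correlation
    as their strength. An empty candidate set yields an empty graph.
    """
    graph = CausalGraph(alpha=alpha, max_lag=max_lag, wetland_type=wetland_type)
    candidates = list(candidates)
    if not candidates:
        return graph
    if driver_parents is None:
        driver_parents = {}
        for d in sorted({c[0] for c in candidates}):
            driver_parents[d] = pc_parent_selection(
                panel, max_lag, alpha, target=d, min_lag=1, cond_cap=cond_cap
            )
    start = 2 * max_lag  # room for parents-of-parents shifts
    links = []
    for X_var, tau in candidates:
        others = [(v, lag) for v, lag in candidates if (v, lag) != (X_var, tau)]
        shifted_parents = [(v, tau + plag) for v, plag in driver_parents.get(X_var, [])]
        # drop duplicates already present among the flux's other parents
        cond_pairs = others + [p for p in shifted_parents if p not in others]
        y, M = panel.lagged([(X_var, tau)] + cond_pairs, TARGET, start)
        try:
            rho, p = partial_correlation(M[:, 0], y, [M[:, i] for i in range(1, M.shape[1])])
        except DegenerateInputError:
            continue
        if p <= alpha:
            links.append(Link(X_var, tau, rho, p))
    graph.links = sorted(links, key=lambda l: (-abs(l.strength), l.driver, l.lag))
    return graph


def infer_graph(
    panel: TimeSeriesPanel,
    max_lag: int = 8,
    alpha: float = 0.05,
    cond_cap: int = 3,
) -> CausalGraph:
    """Full PCMCI run: PC condition selection then MCI tests."""
    cands = pc_parent_selection(panel, max_lag, alpha, cond_cap=cond_cap)
    return mci_tests(
        panel, cands, max_lag, alpha, cond_cap=cond_cap, wetland_type=panel.wetland_type
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def graphs_to_json(graphs: dict, path) -> None:
    """Write per-type graphs to a JSON document (sorted keys, stable bytes)."""
    doc = {wt: g.to_dict() for wt, g in sorted(graphs.items())}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def graphs_from_json(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {wt: CausalGraph.from_dict(d) for wt, d in doc.items()}


def graphs_to_table(graphs: dict, path) -> None:
    """Plain-text table (type, driver, lag, strength, p) of all links."""
    rows = [
        {"wetland_type": wt, "driver": l.driver, "lag": l.lag,
         "strength": l.strength, "p_value": l.p_value}
        for wt, g in sorted(graphs.items()) for l in g.links
    ]
    pd.DataFrame(rows, columns=["wetland_type", "driver", "lag", "strength", "p_value"]).to_csv(
        path, sep="\t", index=False
    )
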