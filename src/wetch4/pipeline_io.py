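"""End-to-end orchestration, configuration and file I/O.

The pipeline sequences the analysis stages::

    simulate -> infer-graph -> train -> upscale -> attribute

writing each stage's outputs to the configured directory and finishing with
a manifest (file list + SHA-256 checksums, config hash, seeds, versions).
Every random element derives from the single master seed, so one config run
twice produces bit-identical outputs. Gridded files are NetCDF (classic
format via the scipy engine) with CF-style units attributes; tables are CSV;
graphs, models and the manifest are JSON.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .attribution import attribute_trend, dominance_map, regional_dominance_summary
from .causal_graph import (CausalGraph, build_panel, graphs_from_json,
                           graphs_to_json, graphs_to_table, infer_graph)
from .errors import InvalidConfigError, SchemaError
from .flux_model import (TrainedModel, evaluate, records_to_observations,
                         site_feature_tables, split_leave_one_site_out,
                         split_random, split_temporal, train_all_types,
                         train_causal_ml)
from .grids import GridSpec, RegionBox, WETLAND_TYPES
from .synthetic_data import (SiteRecord, TruthConfig, generate_drivers,
                             generate_truth_flux, generate_wetlands, sample_sites)
from .upscaling import (linear_trend, monthly_regional_series, predict_grid,
                        seasonal_trend_split, to_regional_annual)
from .grids import region_masks

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["site_id", "wetland_type", "lat", "lon", "frequency",
                "start", "end", "time", "flux"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    grid: dict = field(default_factory=dict)  # GridSpec overrides
    truth: dict = field(default_factory=dict)  # TruthConfig overrides (no seed)
    n_ec: int = 30
    n_chamber: int = 40
    max_lag: int = 8
    alpha: float = 0.05
    cond_cap: int = 3
    lam: float = 0.1
    members: int = 20
    scheme: str = "random"  # random | temporal
    hidden: int = 16
    max_epochs: int = 1500
    seed: int = 0
    regions: dict | None = None  # name -> [lat_min, lat_max, lon_min, lon_max]
    outdir: str = "wetch4_out"

    def __post_init__(self) -> None:
        if self.scheme not in ("random", "temporal", "loo"):
            raise InvalidConfigError(f"unknown scheme {self.scheme!r}")
        if self.members < 1:
            raise InvalidConfigError("members must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.max_lag < 1:
            raise InvalidConfigError("max_lag must be >= 1")
        if self.lam < 0:
            raise InvalidConfigError("lambda must be >= 0")
        self.grid_spec()  # validates grid overrides
        self.truth_config()

    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid)

    def truth_config(self) -> TruthConfig:
        from .synthetic_data import DEFAULT_RESPONSES, TypeResponse

        kw = dict(self.truth)
        if "responses" in kw:
            kw["responses"] = {
                wt: TypeResponse(**r) if isinstance(r, dict) else r
                for wt, r in kw["responses"].items()
            }
        return TruthConfig(seed=self.seed, **kw)

    def region_boxes(self) -> dict | None:
        if self.regions is None:
            return None
        return {name: RegionBox(*box) for name, box in self.regions.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Hash of every scientifically relevant field (outdir excluded)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# gridded file I/O (NetCDF classic via the scipy engine)
# ---------------------------------------------------------------------------

def write_gridded(ds: xr.Dataset, path) -> None:
    """Write a Dataset as classic NetCDF; string type coords become indices."""
    ds = ds.copy()
    if "wetland_type" in ds.coords:
        names = [str(v) for v in ds["wetland_type"].values]
        ds = ds.assign_coords(wetland_type=np.arange(len(names)))
        ds.attrs["wetland_type_names"] = ",".join(names)
    enc = {}
    for v in ds.data_vars:
        if ds[v].dtype == bool:
            ds[v] = ds[v].astype(np.int8)
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_gridded(path, expect_units: bool = True) -> xr.Dataset:
    """Read a gridded file written by :func:`write_gridded`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "wetland_type_names" in ds.attrs:
        names = ds.attrs.pop("wetland_type_names").split(",")
        ds = ds.assign_coords(wetland_type=names)
    if expect_units:
        for v in ds.data_vars:
            if "units" not in ds[v].attrs and not v.endswith(("_sd",)) and v not in (
                "winner", "group", "significant"
            ):
                logger.warning("variable %s carries no units attribute", v)
    return ds


# ---------------------------------------------------------------------------
# site-table I/O
# ---------------------------------------------------------------------------

def write_site_table(records: list, path) -> None:
    """Delimited site table: one row per weekly value, one per chamber mean."""
    rows = []
    for rec in records:
        base = {
            "site_id": rec.site_id, "wetland_type": rec.wetland_type,
            "lat": rec.lat, "lon": rec.lon, "frequency": rec.frequency,
            "start": str(np.datetime64(rec.start, "D")),
            "end": str(np.datetime64(rec.end, "D")),
        }
        if rec.frequency == "weekly":
            times = np.arange(rec.start, rec.end, np.timedelta64(7, "D"))
            for t, v in zip(times, np.asarray(rec.flux, dtype=float)):
                rows.append({**base, "time": str(np.datetime64(t, "D")), "flux": v})
        else:
            rows.append({**base, "time": "", "flux": float(rec.flux)})
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)


def read_site_table(path) -> list:
    """Read and validate a site table back into SiteRecord objects."""
    df = pd.read_csv(path, dtype={"time": str}, keep_default_na=False)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"site table missing column(s): {sorted(missing)}")
    flux = pd.to_numeric(df["flux"], errors="coerce")
    bad = np.nonzero(flux.isna().values)[0]
    if bad.size:
        raise SchemaError(f"non-numeric flux at row {int(bad[0]) + 2} of {path}")
    bad_type = ~df["wetland_type"].isin(WETLAND_TYPES)
    if bad_type.any():
        row = int(np.nonzero(bad_type.values)[0][0]) + 2
        raise SchemaError(f"unknown wetland_type at row {row} of {path}")
    records = []
    for sid, g in df.groupby("site_id", sort=True):
        first = g.iloc[0]
        if first["frequency"] == "weekly":
            g = g.sort_values("time")
            records.append(SiteRecord(
                site_id=sid, wetland_type=first["wetland_type"],
                lat=float(first["lat"]), lon=float(first["lon"]), frequency="weekly",
                start=np.datetime64(first["start"]), end=np.datetime64(first["end"]),
                flux=flux.loc[g.index].values,
            ))
        else:
            records.append(SiteRecord(
                site_id=sid, wetland_type=first["wetland_type"],
                lat=float(first["lat"]), lon=float(first["lon"]), frequency="period_mean",
                start=np.datetime64(first["start"]), end=np.datetime64(first["end"]),
                flux=float(first["flux"]),
            ))
    return records


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def write_models(models: dict, path) -> None:
    doc = {wt: [m.to_jsonable() for m in ms] for wt, ms in sorted(models.items())}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def read_models(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {wt: [TrainedModel.from_jsonable(d) for d in ms] for wt, ms in doc.items()}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    grid = cfg.grid_spec()
    truth_cfg = cfg.truth_config()
    drivers = generate_drivers(grid, truth_cfg)
    wetlands = generate_wetlands(grid, truth_cfg)
    truth = generate_truth_flux(drivers, wetlands, truth_cfg)
    sites = sample_sites(truth, wetlands, cfg.n_ec, cfg.n_chamber, truth_cfg)
    write_gridded(drivers, out / "drivers.nc")
    write_gridded(wetlands, out / "wetlands.nc")
    write_gridded(truth, out / "truth.nc")
    write_site_table(sites, out / "sites.csv")
    return {"files": ["drivers.nc", "wetlands.nc", "truth.nc", "sites.csv"]}


def stage_infer_graph(cfg: PipelineConfig, out: Path) -> dict:
    drivers = read_gridded(out / "drivers.nc")
    records = read_site_table(out / "sites.csv")
    graphs = {}
    for wt in WETLAND_TYPES:
        panel = build_panel(records, drivers, wt)
        if not panel.frames:
            logger.warning("no weekly sites for type %s: empty graph", wt)
            graphs[wt] = CausalGraph(alpha=cfg.alpha, max_lag=cfg.max_lag, wetland_type=wt)
            continue
        graphs[wt] = infer_graph(panel, cfg.max_lag, cfg.alpha, cfg.cond_cap)
    graphs_to_json(graphs, out / "graphs.json")
    graphs_to_table(graphs, out / "graphs.tsv")
    return {"files": ["graphs.json", "graphs.tsv"]}


def stage_train(cfg: PipelineConfig, out: Path) -> dict:
    drivers = read_gridded(out / "drivers.nc")
    records = read_site_table(out / "sites.csv")
    graphs = graphs_from_json(out / "graphs.json")
    rows = []
    if cfg.scheme == "random":
        models, member_metrics, _ = train_all_types(
            records, graphs, drivers, n_members=cfg.members,
            seed=np.random.SeedSequence(entropy=cfg.seed, spawn_key=(100,)),
            lam=cfg.lam, hidden=cfg.hidden, max_epochs=cfg.max_epochs,
        )
        for k, met in enumerate(member_metrics):
            if met is not None:
                rows.append({"member": k, "R": met.R, "MAE": met.MAE,
                             "NMAE": met.NMAE, "n_test": met.n})
    else:  # temporal or leave-one-site-out
        models = {}
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(100,))
        for wt, tseed in zip(WETLAND_TYPES, ss.spawn(len(WETLAND_TYPES))):
            recs = [r for r in records if r.wetland_type == wt]
            obs = records_to_observations(recs)
            if not obs:
                logger.warning("no observations for type %s: skipped", wt)
                continue
            feats = site_feature_tables(recs, drivers, graphs[wt])
            if cfg.scheme == "temporal":
                folds = [split_temporal(obs)]
            else:
                try:
                    folds = list(split_leave_one_site_out(obs))
                except InvalidConfigError:
                    logger.warning("type %s has < 3 sites; single temporal fold", wt)
                    folds = [split_temporal(obs)]
            models[wt] = []
            for k, (tr_all, te) in enumerate(folds):
                s1, s2 = tseed.spawn(2 * k + 2)[-2:]
                tr, va, _ = split_random(tr_all, (0.9, 0.1, 0.0), seed=s1)
                m = train_causal_ml(tr, va, graphs[wt], feats, lam=cfg.lam,
                                    seed=s2, hidden=cfg.hidden,
                                    max_epochs=cfg.max_epochs)
                models[wt].append(m)
                if len(te) >= 2:
                    met = evaluate(m, te, feats)
                    rows.append({"member": f"{wt}-{k}", "R": met.R, "MAE": met.MAE,
                                 "NMAE": met.NMAE, "n_test": met.n})
    write_models(models, out / "models.json")
    pd.DataFrame(rows, columns=["member", "R", "MAE", "NMAE", "n_test"]).to_csv(
        out / "validation.csv", index=False
    )
    return {"files": ["models.json", "validation.csv"]}


def stage_upscale(cfg: PipelineConfig, out: Path) -> dict:
    drivers = read_gridded(out / "drivers.nc")
    wetlands = read_gridded(out / "wetlands.nc")
    models = read_models(out / "models.json")
    for wt in WETLAND_TYPES:  # types with no observations fall back to truth-free skip
        if wt not in models:
            raise InvalidConfigError(f"no model for wetland type {wt}")
    field = predict_grid(models, drivers, wetlands, keep_members=True)
    boxes = cfg.region_boxes()
    annual = to_regional_annual(field, boxes)
    annual.to_csv(out / "regional_annual.csv", index=False)

    rows = []
    for region, g in annual.groupby("region", sort=True):
        tr = linear_trend(pd.Series(g["tg"].values, index=g["year"].values))
        rows.append({"region": region, "slope_tg_per_yr": tr.slope,
                     "p_value": tr.p_value, "percent_change": tr.percent_change,
                     "n_years": tr.n_years})
    pd.DataFrame(rows).to_csv(out / "trends.csv", index=False)

    masks = region_masks(field["lat"].values, field["lon"].values, boxes)
    monthly = monthly_regional_series(field, masks["BA"])
    try:
        frac = seasonal_trend_split(monthly)
        frac.to_frame().to_csv(out / "seasonal_trend_fractions.csv")
    except InvalidConfigError:
        logger.warning("zero annual trend; seasonal split skipped")
    write_gridded(field.drop_vars("member_emission"), out / "flux.nc")
    return {"files": ["flux.nc", "regional_annual.csv", "trends.csv",
                      "seasonal_trend_fractions.csv"]}


def stage_attribute(cfg: PipelineConfig, out: Path) -> dict:
    drivers = read_gridded(out / "drivers.nc")
    wetlands = read_gridded(out / "wetlands.nc")
    field = read_gridded(out / "flux.nc")
    boxes = cfg.region_boxes()
    dom = dominance_map(field, drivers, wetlands, alpha=cfg.alpha)
    write_gridded(dom, out / "dominance.nc")
    regional_dominance_summary(dom, boxes).to_csv(out / "dominance_summary.csv", index=False)
    summary, betas = attribute_trend(field, drivers, wetlands, regions=boxes)
    summary.to_csv(out / "trend_attribution.csv", index=False)
    write_gridded(betas, out / "trend_betas.nc")
    return {"files": ["dominance.nc", "dominance_summary.csv",
                      "trend_attribution.csv", "trend_betas.nc"]}


STAGES = [
    ("simulate", stage_simulate),
    ("infer-graph", stage_infer_graph),
    ("train", stage_train),
    ("upscale", stage_upscale),
    ("attribute", stage_attribute),
]


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the pipeline (all stages by default) and write the manifest.

    Stages read their inputs from the output directory, so a subset list can
    resume from existing intermediate files. Any stage failure aborts with
    the stage name attached to the exception.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = {s for s in (stages or [name for name, _ in STAGES])}
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"wetch4": __version__, "numpy": np.__version__},
        "stages": [],
        "files": {},
    }
    for name, fn in STAGES:
        if name not in wanted:
            continue
        logger.info("stage %s", name)
        try:
            info = fn(cfg, out)
        except Exception as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        for f in info["files"]:
            p = out / f
            if p.exists():
                manifest["files"][f] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
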