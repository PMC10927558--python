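"""Causality-guided flux regressors trained on mixed-frequency observations.

One model per wetland type. The feature set is dictated by the type's causal
graph — one column per retained (driver, lag) link — and training minimizes

    mean mixed-frequency loss + lambda * causal-guidance penalty

where weekly (eddy-covariance) observations contribute pointwise squared
errors, period-mean (chamber) observations contribute the squared error
between the model's window-mean prediction and the reported mean, and the
guidance penalty is a sign-consistency hinge: the model's mean
finite-difference sensitivity to each causal feature must agree in sign with
the link's partial-correlation strength. Features are standardized by the
training-set mean/s.d.; predictions are returned in physical units
(nmol CH4 m-2 s-1).

An ensemble of members, each with its own random 80/10/10 split and
initialization, provides the headline estimate (member mean) and the
parameter uncertainty (member s.d.).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _mlp
from .causal_graph import CausalGraph
from .errors import InvalidConfigError
from .grids import DRIVERS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Observation:
    """One flux observation: a single week of an EC series, or one chamber mean."""

    site_id: str
    wetland_type: str
    kind: str  # 'weekly' | 'period_mean'
    value: float
    time: np.datetime64 | None = None  # weekly only
    start: np.datetime64 | None = None  # period_mean only
    end: np.datetime64 | None = None


def records_to_observations(records) -> list[Observation]:
    """Explode site records into individual observations.

    Weekly EC series become one observation per week; chamber records stay a
    single period-mean observation.
    """
    obs: list[Observation] = []
    for rec in records:
        if rec.frequency == "weekly":
            times = np.arange(rec.start, rec.end, np.timedelta64(7, "D"))
            vals = np.asarray(rec.flux, dtype=float)
            for t, v in zip(times, vals):
                obs.append(Observation(rec.site_id, rec.wetland_type, "weekly", float(v), time=t))
        else:
            obs.append(
                Observation(rec.site_id, rec.wetland_type, "period_mean", float(rec.flux),
                            start=rec.start, end=rec.end)
            )
    return obs


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def feature_pairs(graph: CausalGraph) -> list[tuple[str, int]]:
    """Feature spec from a graph; empty graphs fall back to all drivers at lag 0."""
    pairs = sorted(graph.pairs(), key=lambda c: (c[0], c[1]))
    if not pairs:
        logger.warning("empty causal graph (%s): falling back to all drivers at lag 0",
                       graph.wetland_type or "?")
        pairs = [(d, 0) for d in DRIVERS]
    return pairs


def build_features(drivers_at_site: pd.DataFrame, graph: CausalGraph) -> pd.DataFrame:
    """Lagged feature matrix for one site/cell.

    ``drivers_at_site`` is a weekly DataFrame (time index, driver columns).
    Output has one column per (driver, lag) named ``"DRV-lag"``; the leading
    rows lacking full lag history are dropped.
    """
    pairs = feature_pairs(graph)
    max_lag = max((lag for _, lag in pairs), default=0)
    n = len(drivers_at_site)
    if n <= max_lag:
        logger.warning("series of %d weeks shorter than max feature lag %d", n, max_lag)
        return pd.DataFrame(
            columns=[f"{d}-{lag}" for d, lag in pairs], index=drivers_at_site.index[:0]
        )
    idx = np.arange(max_lag, n)
    cols = {
        f"{d}-{lag}": drivers_at_site[d].values[idx - lag] for d, lag in pairs
    }
    return pd.DataFrame(cols, index=drivers_at_site.index[max_lag:])


def site_feature_tables(records, drivers, graph: CausalGraph) -> dict:
    """Per-site feature tables from the driver cube at each site's cell."""
    tables = {}
    times = pd.DatetimeIndex(drivers["time"].values)
    for rec in records:
        if rec.site_id in tables:
            continue
        i = int(np.argmin(np.abs(drivers["lat"].values - rec.lat)))
        j = int(np.argmin(np.abs(drivers["lon"].values - rec.lon)))
        df = pd.DataFrame({d: drivers[d].values[:, i, j] for d in DRIVERS}, index=times)
        tables[rec.site_id] = build_features(df, graph)
    return tables


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """One causality-guided regressor for a single wetland type."""

    wetland_type: str
    pairs: list  # ordered (driver, lag) feature spec
    signs: np.ndarray  # per-feature causal-strength sign (0 = unconstrained)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    params: _mlp.MLPParams
    meta: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return [f"{d}-{lag}" for d, lag in self.pairs]

    def predict(self, X) -> np.ndarray:
        """Flux prediction (physical units) for a feature matrix/DataFrame."""
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].values
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return _mlp.forward(self.params, Xs) * self.y_sd + self.y_mean

    def to_jsonable(self) -> dict:
        return {
            "wetland_type": self.wetland_type,
            "pairs": [[d, int(lag)] for d, lag in self.pairs],
            "signs": self.signs.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "params": self.params.to_jsonable(),
            "meta": self.meta,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "TrainedModel":
        return cls(
            wetland_type=d["wetland_type"],
            pairs=[(p[0], int(p[1])) for p in d["pairs"]],
            signs=np.asarray(d["signs"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            params=_mlp.MLPParams.from_jsonable(d["params"]),
            meta=d.get("meta", {}),
        )


def learned_sensitivities(model: TrainedModel, probe) -> np.ndarray:
    """Mean finite-difference sensitivity of the prediction to each feature.

    Step size is half the probe column s.d. (physical units); zero-variance
    columns get NaN.
    """
    if isinstance(probe, pd.DataFrame):
        probe = probe[model.columns].values
    probe = np.asarray(probe, dtype=float)
    sd = probe.std(axis=0)
    out = np.full(probe.shape[1], np.nan)
    for j in range(probe.shape[1]):
        if sd[j] <= 1e-12:
            logger.warning("zero-variance probe column %s skipped", model.columns[j])
            continue
        h = 0.5 * sd[j]
        e = np.zeros(probe.shape[1])
        e[j] = h
        out[j] = float(np.mean(model.predict(probe + e) - model.predict(probe - e))) / (2 * h)
    return out


def causal_guidance_penalty(model: TrainedModel, graph: CausalGraph, probe) -> float:
    """Sign-consistency hinge penalty of a trained model against its graph.

    Zero iff every learned sensitivity agrees in sign with its link's MCI
    strength; disagreeing links contribute the squared sensitivity
    magnitude (computed on predictions standardized by the model's target
    scale, so the value is dimensionless).
    """
    if isinstance(probe, pd.DataFrame):
        probe = probe[model.columns].values
    if probe is None or len(probe) == 0:
        raise InvalidConfigError("probe matrix must be non-empty")
    strength = {(l.driver, l.lag): l.strength for l in graph.links}
    S = learned_sensitivities(model, probe)
    penalty = 0.0
    for j, pair in enumerate(model.pairs):
        s = strength.get(pair)
        if s is None or np.isnan(S[j]):
            continue
        viol = max(0.0, -np.sign(s) * S[j] / model.y_sd)
        penalty += viol**2
    return penalty


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_random(observations, fractions=(0.8, 0.1, 0.1), seed=0):
    """Random (train, val, test) split at the observation level, stratified by site."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidConfigError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_site: dict = {}
    for k, o in enumerate(observations):
        by_site.setdefault(o.site_id, []).append(k)
    train, val, test = [], [], []
    for sid in sorted(by_site):
        idx = np.array(by_site[sid])
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n)
        n_va = min(n_va, n - n_tr)
        train += [observations[i] for i in idx[:n_tr]]
        val += [observations[i] for i in idx[n_tr:n_tr + n_va]]
        test += [observations[i] for i in idx[n_tr + n_va:]]
    # single-observation sites can starve the validation split; training
    # requires one, so borrow the last training observation deterministically
    if not val and fractions[1] > 0 and len(train) >= 2:
        val.append(train.pop())
    return train, val, test


def split_leave_one_site_out(observations):
    """Iterator of (train, test) folds, one per site; test = the whole site."""
    sites = sorted({o.site_id for o in observations})
    if len(sites) < 3:
        raise InvalidConfigError("leave-one-out needs >= 3 sites")
    for sid in sites:
        test = [o for o in observations if o.site_id == sid]
        train = [o for o in observations if o.site_id != sid]
        yield train, test


def split_temporal(observations, test_fraction: float = 0.2):
    """Per-site temporal split: each site's final contiguous weeks are test.

    Period-mean observations (no weekly time axis) stay in the training set.
    """
    if not any(o.kind == "weekly" for o in observations):
        raise InvalidConfigError("temporal split needs weekly records")
    by_site: dict = {}
    for o in observations:
        by_site.setdefault(o.site_id, []).append(o)
    train, test = [], []
    for sid in sorted(by_site):
        obs = by_site[sid]
        weekly = sorted([o for o in obs if o.kind == "weekly"], key=lambda o: o.time)
        n_test = int(round(test_fraction * len(weekly)))
        cut = len(weekly) - n_test
        train += [o for o in obs if o.kind != "weekly"] + weekly[:cut]
        test += weekly[cut:]
    return train, test


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _assemble(observations, features: dict):
    """(X_weekly, y_weekly, period_groups) arrays from observations."""
    Xw, yw, groups = [], [], []
    dropped = 0
    for o in observations:
        tab = features.get(o.site_id)
        if tab is None or tab.empty:
            dropped += 1
            continue
        if o.kind == "weekly":
            t = pd.Timestamp(o.time)
            if t not in tab.index:
                dropped += 1
                continue
            Xw.append(tab.loc[t].values)
            yw.append(o.value)
        else:
            sel = (tab.index >= pd.Timestamp(o.start)) & (tab.index < pd.Timestamp(o.end))
            if not sel.any():
                dropped += 1
                continue
            groups.append((tab.values[sel], o.value))
    if dropped:
        logger.warning("%d observations dropped for missing lag history", dropped)
    Xw = np.vstack(Xw) if Xw else np.empty((0, next(iter(features.values())).shape[1]))
    return Xw, np.asarray(yw, dtype=float), groups


def _graph_signs(pairs, graph: CausalGraph) -> np.ndarray:
    strength = {(l.driver, l.lag): l.strength for l in graph.links}
    return np.array([np.sign(strength.get(p, 0.0)) for p in pairs])


def train_causal_ml(
    train, val, graph: CausalGraph, features: dict,
    lam: float = 0.1, seed=0, hidden: int = 16, max_epochs: int = 1500,
    lr: float = 0.02, patience: int = 20,
) -> TrainedModel:
    """Train one causality-guided regressor.

    ``features`` maps site_id -> feature table (from
    :func:`site_feature_tables`); ``train``/``val`` are observation lists.
    """
    if lam < 0:
        raise InvalidConfigError("lambda must be >= 0")
    if not train:
        raise InvalidConfigError("empty training set")
    if not val:
        raise InvalidConfigError("this scheme requires a validation set")
    pairs = feature_pairs(graph)
    Xw, yw, groups = _assemble(train, features)
    Xv, yv, vgroups = _assemble(val, features)

    all_rows = np.vstack([Xw] + [g[0] for g in groups]) if (Xw.size or groups) else Xw
    x_mean = all_rows.mean(axis=0)
    x_sd = all_rows.std(axis=0)
    x_sd = np.where(x_sd <= 1e-12, 1.0, x_sd)
    y_all = np.concatenate([yw, [g[1] for g in groups]])
    y_mean = float(y_all.mean())
    y_sd = float(y_all.std())
    y_sd = y_sd if y_sd > 1e-12 else 1.0

    def std_X(X):
        return (X - x_mean) / x_sd

    def std_y(y):
        return (np.asarray(y) - y_mean) / y_sd

    fit = _mlp.fit(
        std_X(Xw), std_y(yw), [(std_X(g[0]), float(std_y(g[1]))) for g in groups],
        std_X(Xv), std_y(yv), [(std_X(g[0]), float(std_y(g[1]))) for g in vgroups],
        signs=_graph_signs(pairs, graph),
        lam=lam, hidden=hidden, seed=seed, lr=lr,
        max_epochs=max_epochs, patience=patience,
    )
    return TrainedModel(
        wetland_type=graph.wetland_type,
        pairs=pairs,
        signs=_graph_signs(pairs, graph),
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        params=fit.params,
        meta={
            "lam": lam, "hidden": hidden,
            "n_train": len(train), "n_val": len(val),
            "val_loss": fit.val_loss, "n_epochs": fit.n_epochs,
        },
    )


def ensemble_train(
    observations, graph: CausalGraph, features: dict,
    n_members: int = 20, seed=0, lam: float = 0.1, hidden: int = 16,
    max_epochs: int = 1500, fractions=(0.8, 0.1, 0.1),
):
    """Train an ensemble of members with independent random splits.

    Returns ``(models, metrics)``: one TrainedModel and one EvalMetrics (on
    the member's own held-out 10%) per member.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(entropy=seed)
    children = ss.spawn(n_members)
    models, metrics = [], []
    for m, child in enumerate(children):
        split_seed, train_seed = child.spawn(2)
        tr, va, te = split_random(observations, fractions, seed=split_seed)
        model = train_causal_ml(tr, va, graph, features, lam=lam,
                                seed=train_seed, hidden=hidden, max_epochs=max_epochs)
        model.meta["member"] = m
        models.append(model)
        metrics.append(evaluate(model, te, features) if te else None)
    return models, metrics


def train_all_types(
    records, graphs: dict, drivers, n_members: int = 20, seed=0,
    lam: float = 0.1, hidden: int = 16, max_epochs: int = 1500,
):
    """Train per-type ensembles and pool each member's held-out validation.

    Mirrors the study design: every member gets its own random 80/10/10
    split per type, and the member's held-out predictions are pooled across
    wetland types before computing R / MAE / NMAE (site observations of all
    types validate the upscaling jointly).

    Returns ``(models, member_metrics, features)`` where ``models`` maps
    type -> list of models, ``member_metrics`` is one pooled EvalMetrics per
    member, and ``features`` maps type -> site feature tables.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(entropy=seed)
    type_seeds = dict(zip(sorted(graphs), ss.spawn(len(graphs))))
    models: dict = {}
    features: dict = {}
    member_tests: list = [[] for _ in range(n_members)]
    for wt in sorted(graphs):
        recs = [r for r in records if r.wetland_type == wt]
        obs = records_to_observations(recs)
        if not obs:
            logger.warning("no observations for type %s", wt)
            continue
        feats = site_feature_tables(recs, drivers, graphs[wt])
        features[wt] = feats
        models[wt] = []
        for k, child in enumerate(type_seeds[wt].spawn(n_members)):
            split_seed, train_seed = child.spawn(2)
            tr, va, te = split_random(obs, seed=split_seed)
            m = train_causal_ml(tr, va, graphs[wt], feats, lam=lam,
                                seed=train_seed, hidden=hidden, max_epochs=max_epochs)
            m.meta["member"] = k
            models[wt].append(m)
            member_tests[k].append((m, te, feats))
    member_metrics = []
    for k in range(n_members):
        pairs = []
        for m, te, feats in member_tests[k]:
            pairs += _prediction_pairs(m, te, feats)
        member_metrics.append(_metrics_from_pairs(pairs) if len(pairs) >= 2 else None)
    return models, member_metrics, features


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    """Pearson R, mean absolute error, and range-normalized MAE (percent)."""

    R: float
    MAE: float  # nmol CH4 m-2 s-1
    NMAE: float  # percent of the observed test-flux range
    n: int


def _ensemble_predict(models, X) -> np.ndarray:
    if isinstance(models, TrainedModel):
        return models.predict(X)
    return np.mean([m.predict(X) for m in models], axis=0)


def _prediction_pairs(models, test, features: dict) -> list:
    """(prediction, observation) pairs; weekly pointwise, chamber as window means."""
    pairs = []
    for o in test:
        tab = features.get(o.site_id)
        if tab is None or tab.empty:
            continue
        if o.kind == "weekly":
            t = pd.Timestamp(o.time)
            if t not in tab.index:
                continue
            pairs.append((float(_ensemble_predict(models, tab.loc[[t]])[0]), o.value))
        else:
            sel = (tab.index >= pd.Timestamp(o.start)) & (tab.index < pd.Timestamp(o.end))
            if not sel.any():
                continue
            pairs.append((float(_ensemble_predict(models, tab[sel]).mean()), o.value))
    return pairs


def _metrics_from_pairs(pairs) -> EvalMetrics:
    preds, obs = np.asarray(pairs, dtype=float).T
    mae = float(np.mean(np.abs(preds - obs)))
    rng = float(obs.max() - obs.min())
    r = float(stats.pearsonr(preds, obs).statistic) if preds.std() > 0 and obs.std() > 0 else np.nan
    return EvalMetrics(R=r, MAE=mae, NMAE=100.0 * mae / rng if rng > 0 else np.nan, n=obs.size)


def evaluate(models, test, features: dict) -> EvalMetrics:
    """Pool weekly pointwise and period window-mean comparisons into metrics."""
    pairs = _prediction_pairs(models, test, features)
    if len(pairs) < 2:
        raise InvalidConfigError("need >= 2 evaluable observations")
    return _metrics_from_pairs(pairs)
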