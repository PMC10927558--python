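"""Feature building, guidance penalty, splits, training and evaluation."""
import numpy as np
import pandas as pd
import pytest

import wetch4 as w
from wetch4 import _mlp
from wetch4.causal_graph import CausalGraph, Link
from wetch4.errors import InvalidConfigError
from wetch4.flux_model import (Observation, TrainedModel, build_features,
                               causal_guidance_penalty, evaluate,
                               learned_sensitivities, records_to_observations,
                               split_leave_one_site_out, split_random,
                               split_temporal, train_causal_ml)


def graph_of(pairs, strengths=None, wetland_type="fen"):
    strengths = strengths or [0.5] * len(pairs)
    return CausalGraph(
        links=[Link(d, lag, s, 0.01) for (d, lag), s in zip(pairs, strengths)],
        alpha=0.05, max_lag=8, wetland_type=wetland_type,
    )


def driver_frame(n, rng):
    idx = pd.date_range("2002-01-01", periods=n, freq="7D")
    return pd.DataFrame({d: rng.standard_normal(n) for d in w.DRIVERS}, index=idx)


def linearish_model(coefs, pairs):
    """Hand-built TrainedModel computing ~sum_j coef_j x_j (tanh near origin)."""
    eps = 1e-3
    k = len(pairs)
    params = _mlp.MLPParams(
        W1=eps * np.eye(k), b1=np.zeros(k),
        w2=np.asarray(coefs, dtype=float) / eps, b2=0.0,
    )
    return TrainedModel(
        wetland_type="fen", pairs=list(pairs), signs=np.sign(coefs),
        x_mean=np.zeros(k), x_sd=np.ones(k), y_mean=0.0, y_sd=1.0, params=params,
    )


class TestBuildFeatures:
    def test_lag_zero_column_equals_driver(self, rng):
        df = driver_frame(20, rng)
        X = build_features(df, graph_of([("TS", 0)]))
        np.testing.assert_array_equal(X["TS-0"].values, df["TS"].values)

    def test_lag_shift_semantics_and_row_drop(self, rng):
        df = driver_frame(20, rng)
        X = build_features(df, graph_of([("TS", 2)]))
        assert len(X) == 18  # first 2 rows lack history
        np.testing.assert_array_equal(X["TS-2"].values, df["TS"].values[:-2])
        assert X.index[0] == df.index[2]

    def test_row_count_ten_week_window_two_links(self, rng):
        df = driver_frame(10, rng)
        X = build_features(df, graph_of([("TS", 3), ("GPP", 1)]))
        assert X.shape == (7, 2)

    def test_empty_graph_falls_back_to_all_drivers_lag0(self, rng):
        df = driver_frame(15, rng)
        X = build_features(df, CausalGraph(wetland_type="bog"))
        assert X.shape == (15, 8)


class TestGuidancePenalty:
    def test_sign_agreement_gives_zero(self, rng):
        pairs = [("TS", 0), ("GPP", 2)]
        model = linearish_model([1.5, 0.7], pairs)
        g = graph_of(pairs, strengths=[0.6, 0.3])
        probe = rng.standard_normal((50, 2))
        assert causal_guidance_penalty(model, g, probe) == 0.0

    def test_forced_disagreement_is_positive(self, rng):
        pairs = [("TS", 0)]
        model = linearish_model([-1.0], pairs)  # learner = -x
        g = graph_of(pairs, strengths=[0.6])
        probe = rng.standard_normal((50, 1))
        pen = causal_guidance_penalty(model, g, probe)
        S = learned_sensitivities(model, probe)
        assert pen == pytest.approx(S[0] ** 2, rel=1e-6)
        assert pen > 0.5

    def test_zero_status_invariant_to_feature_rescaling(self, rng):
        pairs = [("TS", 0), ("GPP", 1)]
        probe = rng.standard_normal((60, 2))
        for coefs in ([1.0, 1.0], [-1.0, 1.0]):
            model = linearish_model(coefs, pairs)
            g = graph_of(pairs, strengths=[0.5, 0.5])
            p1 = causal_guidance_penalty(model, g, probe)
            p2 = causal_guidance_penalty(model, g, 2.0 * probe)
            assert (p1 == 0.0) == (p2 == 0.0)

    def test_empty_probe_rejected(self, rng):
        model = linearish_model([1.0], [("TS", 0)])
        with pytest.raises(InvalidConfigError):
            causal_guidance_penalty(model, graph_of([("TS", 0)]), np.empty((0, 1)))


def make_observations(n_sites=5, weeks=40, rng=None):
    obs = []
    t0 = np.datetime64("2002-01-01")
    for s in range(n_sites):
        for k in range(weeks):
            obs.append(Observation(f"S{s}", "fen", "weekly",
                                   float(rng.standard_normal()),
                                   time=t0 + np.timedelta64(7 * k, "D")))
    return obs


class TestSplits:
    def test_random_80_10_10_counts(self, rng):
        obs = make_observations(5, 20, rng)  # 100 records
        tr, va, te = split_random(obs, seed=3)
        assert len(tr) + len(va) + len(te) == 100
        assert abs(len(tr) - 80) <= 5 and abs(len(va) - 10) <= 5
        # stratified: every site appears in train
        assert {o.site_id for o in tr} == {f"S{s}" for s in range(5)}

    def test_random_split_disjoint_and_seeded(self, rng):
        obs = make_observations(4, 30, rng)
        a = split_random(obs, seed=1)
        b = split_random(obs, seed=1)
        assert a == b
        ids = [id(o) for part in a for o in part]
        assert len(ids) == len(set(ids))

    def test_bad_fractions_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            split_random(make_observations(2, 5, rng), fractions=(0.7, 0.1, 0.1))

    def test_leave_one_out_folds(self, rng):
        obs = make_observations(5, 10, rng)
        folds = list(split_leave_one_site_out(obs))
        assert len(folds) == 5
        for tr, te in folds:
            assert len({o.site_id for o in te}) == 1
            assert {o.site_id for o in te}.isdisjoint({o.site_id for o in tr})

    def test_temporal_split_takes_final_fifth(self, rng):
        obs = make_observations(1, 50, rng)
        tr, te = split_temporal(obs)
        assert len(te) == 10
        assert min(o.time for o in te) > max(o.time for o in tr)


class TestTraining:
    def make_linear_problem(self, rng, n_sites=4, weeks=120, noise=0.0):
        pairs = [("TS", 0), ("GPP", 2)]
        graph = graph_of(pairs, strengths=[0.6, 0.4])
        feats, obs = {}, []
        for s in range(n_sites):
            df = driver_frame(weeks, rng)
            X = build_features(df, graph)
            feats[f"S{s}"] = X
            y = 2.0 * X["TS-0"].values + 1.0 * X["GPP-2"].values + 5.0 \
                + noise * rng.standard_normal(len(X))
            for t, v in zip(X.index, y):
                obs.append(Observation(f"S{s}", "fen", "weekly", float(v),
                                       time=np.datetime64(t, "D")))
        return graph, feats, obs

    def test_noiseless_linear_truth_recovered(self, rng):
        graph, feats, obs = self.make_linear_problem(rng)
        tr, va, te = split_random(obs, seed=0)
        model = train_causal_ml(tr, va, graph, feats, lam=0.0, seed=0)
        met = evaluate(model, te, feats)
        assert met.R >= 0.99

    def test_seeded_training_is_deterministic(self, rng):
        graph, feats, obs = self.make_linear_problem(rng, n_sites=2, weeks=60, noise=0.3)
        tr, va, _ = split_random(obs, seed=0)
        m1 = train_causal_ml(tr, va, graph, feats, seed=11, max_epochs=300)
        m2 = train_causal_ml(tr, va, graph, feats, seed=11, max_epochs=300)
        np.testing.assert_array_equal(m1.params.W1, m2.params.W1)
        np.testing.assert_array_equal(m1.params.w2, m2.params.w2)

    def test_period_mean_records_enter_the_objective(self, rng):
        """Chamber window means constrain the model where weekly data are absent."""
        graph, feats, obs = self.make_linear_problem(rng, n_sites=3, weeks=80)
        # replace one site's weekly records by a single period mean
        sid = "S0"
        weekly = [o for o in obs if o.site_id == sid]
        mean = float(np.mean([o.value for o in weekly]))
        t0, t1 = min(o.time for o in weekly), max(o.time for o in weekly)
        chamber = Observation(sid, "fen", "period_mean", mean,
                              start=t0, end=t1 + np.timedelta64(7, "D"))
        rest = [o for o in obs if o.site_id != sid]
        tr, va, _ = split_random(rest, seed=1)
        model = train_causal_ml(tr + [chamber], va, graph, feats, lam=0.0, seed=0)
        # window-mean prediction reproduces the chamber mean
        tab = feats[sid]
        pred = float(model.predict(tab).mean())
        assert pred == pytest.approx(mean, abs=0.3)

    def test_large_lambda_enforces_sign_consistency(self, rng):
        """With adversarial sign-flipped labels the hinge dominates training."""
        pairs = [("TS", 0)]
        graph = graph_of(pairs, strengths=[0.8])  # causal strength positive
        df = driver_frame(150, rng)
        X = build_features(df, graph)
        y = -2.0 * X["TS-0"].values  # labels contradict the causal sign
        feats = {"S0": X}
        obs = [Observation("S0", "fen", "weekly", float(v), time=np.datetime64(t, "D"))
               for t, v in zip(X.index, y)]
        tr, va, _ = split_random(obs, seed=0)
        free = train_causal_ml(tr, va, graph, feats, lam=0.0, seed=0, max_epochs=400)
        forced = train_causal_ml(tr, va, graph, feats, lam=200.0, seed=0, max_epochs=400)
        probe = X.values
        s_free = learned_sensitivities(free, probe)[0]
        s_forced = learned_sensitivities(forced, probe)[0]
        assert s_free < -1.5  # unconstrained fit follows the flipped labels
        # quadratic hinge: equilibrium sits at a vanishing violation
        assert s_forced > -0.05
        assert abs(s_forced) < 0.05 * abs(s_free)

    def test_empty_val_rejected(self, rng):
        graph, feats, obs = self.make_linear_problem(rng, n_sites=2, weeks=40)
        with pytest.raises(InvalidConfigError):
            train_causal_ml(obs, [], graph, feats)


class TestEvaluate:
    def make_eval_case(self, rng, shift=0.0):
        pairs = [("TS", 0)]
        df = driver_frame(30, rng)
        X = build_features(df, graph_of(pairs))
        y = X["TS-0"].values.astype(float)
        model = linearish_model([1.0], pairs)
        feats = {"S0": X}
        obs = [Observation("S0", "fen", "weekly", float(v + shift),
                           time=np.datetime64(t, "D")) for t, v in zip(X.index, y)]
        return model, obs, feats, y

    def test_perfect_predictions(self, rng):
        model, obs, feats, _ = self.make_eval_case(rng)
        met = evaluate(model, obs, feats)
        assert met.R == pytest.approx(1.0, abs=1e-5)
        assert met.MAE == pytest.approx(0.0, abs=1e-5)
        assert met.NMAE == pytest.approx(0.0, abs=1e-4)

    def test_constant_shift_keeps_r(self, rng):
        model, obs, feats, _ = self.make_eval_case(rng, shift=3.0)
        met = evaluate(model, obs, feats)
        assert met.R == pytest.approx(1.0, abs=1e-5)
        assert met.MAE == pytest.approx(3.0, abs=1e-4)

    def test_mae_matches_brute_force(self, rng):
        model, obs, feats, y = self.make_eval_case(rng)
        noisy = [Observation(o.site_id, o.wetland_type, o.kind,
                             o.value + float(rng.standard_normal()), time=o.time)
                 for o in obs]
        met = evaluate(model, noisy, feats)
        preds = model.predict(feats["S0"])
        expected = float(np.mean(np.abs(preds - np.array([o.value for o in noisy]))))
        assert met.MAE == pytest.approx(expected, abs=1e-12)


def test_records_to_observations_explodes_weekly(scene):
    *_, sites = scene
    obs = records_to_observations(sites)
    n_weekly = sum(len(np.atleast_1d(r.flux)) for r in sites if r.frequency == "weekly")
    n_chamber = sum(1 for r in sites if r.frequency == "period_mean")
    assert len(obs) == n_weekly + n_chamber
    kinds = {o.kind for o in obs}
    assert kinds == {"weekly", "period_mean"}


def test_model_json_round_trip(rng):
    model = linearish_model([1.0, -0.5], [("TS", 0), ("SC", 4)])
    clone = TrainedModel.from_jsonable(model.to_jsonable())
    X = rng.standard_normal((10, 2))
    np.testing.assert_array_equal(model.predict(X), clone.predict(X))
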