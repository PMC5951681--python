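"""GDM pair tables, constrained fitting, prediction and spline curves."""

import numpy as np
import pandas as pd
import pytest

import yellowbox as yb
from yellowbox.distances import PairwiseMatrix
from yellowbox.gdm import (
    GEO,
    GDMModel,
    fit_gdm,
    fit_gdm_design,
    make_pair_table,
    null_deviance,
)
from yellowbox.sites import SiteTable


def scaled_response(labels, values):
    return PairwiseMatrix(labels, values, "scaled_fst")


@pytest.fixture()
def toy_setup(toy_sites):
    geo = yb.geographic_distance(toy_sites)
    rng = np.random.default_rng(5)
    v = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    v[iu] = rng.uniform(0.1, 0.9, 6)
    v += v.T
    return toy_sites, scaled_response(toy_sites.site_ids, v), geo


class TestMakePairTable:
    def test_row_count(self, toy_setup):
        sites, resp, geo = toy_setup
        pt = make_pair_table(sites, ["temp", "rain"], resp, geo)
        assert len(pt.df) == 6  # S(S-1)/2

    def test_identical_pair_is_zero_row(self):
        df = pd.DataFrame(
            {
                "lat": [-35.0, -35.0, -34.0, -33.0],
                "lon": [147.0, 147.0, 147.5, 148.0],
                "temp": [10.0, 10.0, 14.0, 18.0],
            },
            index=pd.Index(list("ABCD"), name="site_id"),
        )
        sites = SiteTable(df)
        geo = yb.geographic_distance(sites)
        rng = np.random.default_rng(0)
        v = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        v[iu] = rng.uniform(0, 1, 6)
        v += v.T
        pt = make_pair_table(sites, ["temp"], scaled_response(sites.site_ids, v), geo)
        row = pt.df.iloc[0]  # pair (A, B): same env, same location
        assert (row[pt.design_columns] == 0).all()

    def test_matches_nested_loop_construction(self, toy_setup):
        sites, resp, geo = toy_setup
        preds = ["temp", "rain"]
        pt = make_pair_table(sites, preds, resp, geo)
        env = sites.env_values(preds)
        ids = sites.site_ids
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                row = pt.df.iloc[k]
                assert row["site_a"] == ids[i] and row["site_b"] == ids[j]
                assert row["d"] == resp.values[i, j]
                for p in preds:
                    iv = pt.bases[p].evaluate(
                        np.array([env[p].iloc[i], env[p].iloc[j]])
                    )
                    for b in range(3):
                        assert row[f"{p}__i{b}"] == pytest.approx(
                            abs(iv[0, b] - iv[1, b])
                        )
                gv = pt.bases[GEO].evaluate(geo.values[i, j])
                for b in range(3):
                    assert row[f"{GEO}__i{b}"] == pytest.approx(gv[b])
                k += 1

    def test_missing_env_value_names_site_and_variable(self, toy_sites):
        df = toy_sites.df.copy()
        df.loc["B", "rain"] = np.nan
        sites = SiteTable(df)
        geo = yb.geographic_distance(sites)
        v = np.eye(4) * 0
        v[0, 1] = v[1, 0] = 0.5
        with pytest.raises(ValueError, match="B.*rain"):
            make_pair_table(sites, ["temp", "rain"], scaled_response(sites.site_ids, v), geo)


class TestFitGdm:
    def test_all_zero_response_is_degenerate(self, toy_setup):
        sites, resp, geo = toy_setup
        zero = scaled_response(sites.site_ids, np.zeros((4, 4)))
        model = fit_gdm(make_pair_table(sites, ["temp"], zero, geo))
        assert model.degenerate
        assert model.intercept == 0.0
        assert all(np.all(c == 0) for c in model.coefficients.values())
        assert model.deviance_explained == 0.0

    def test_grid_search_oracle_single_predictor(self):
        """On a 6-pair, one-column problem the Gauss-Newton/NNLS fit must
        match a dense grid search over (b0, b) in [0,3]^2 at 1e-3."""
        x = np.array([0.05, 0.2, 0.35, 0.5, 0.8, 1.0])[:, None]
        rng = np.random.default_rng(42)
        d = np.clip(1 - np.exp(-(0.1 + 0.9 * x[:, 0])) + rng.normal(0, 0.03, 6), 0, 1)
        beta, dev, _ = fit_gdm_design(x, d)

        grid = np.arange(0, 3.0 + 1e-9, 1e-3)
        best = (np.inf, None, None)
        chunk = 200
        for s in range(0, grid.size, chunk):
            b0 = grid[s : s + chunk][:, None, None]
            b1 = grid[None, :, None]
            eta = b0 + b1 * x[:, 0][None, None, :]
            devs = ((d[None, None, :] - (1 - np.exp(-eta))) ** 2).sum(axis=2)
            k = np.unravel_index(np.argmin(devs), devs.shape)
            if devs[k] < best[0]:
                best = (devs[k], grid[s + k[0]], grid[k[1]])
        grid_dev, g0, g1 = best
        assert dev <= grid_dev + 1e-9
        assert beta[0] == pytest.approx(g0, abs=2e-3)
        assert beta[1] == pytest.approx(g1, abs=2e-3)

    def test_noiseless_self_consistency(self, toy_setup):
        """Response generated from known coefficients on the pair table is
        recovered exactly on the prediction scale."""
        sites, resp, geo = toy_setup
        pt = make_pair_table(sites, ["temp", "rain"], resp, geo)
        x = pt.design()
        true_beta = np.array([0.08, 0.3, 0.1, 0.0, 0.2, 0.05, 0.15, 0.4, 0.1, 0.0])
        mu = 1 - np.exp(-(true_beta[0] + x @ true_beta[1:]))
        pt.df["d"] = mu
        model = fit_gdm(pt)
        xt = np.column_stack([np.ones(len(mu)), x])
        beta_hat = np.concatenate(
            [[model.intercept]] + [model.coefficients[p] for p in ["temp", "rain", GEO]]
        )
        mu_hat = 1 - np.exp(-(xt @ beta_hat))
        assert np.max(np.abs(mu_hat - mu)) < 1e-6

    def test_response_out_of_range_rejected(self, toy_setup):
        sites, resp, geo = toy_setup
        bad = resp.values.copy()
        bad[0, 1] = bad[1, 0] = 1.4
        with pytest.raises(ValueError, match="0, 1"):
            fit_gdm(make_pair_table(sites, ["temp"], scaled_response(sites.site_ids, bad), geo))

    def test_coefficients_non_negative(self, small_world_gdm):
        model = small_world_gdm["model"]
        assert model.intercept >= 0
        for c in model.coefficients.values():
            assert np.all(c >= 0)

    def test_deterministic(self, small_world_gdm):
        m1 = fit_gdm(small_world_gdm["pair_table"])
        m2 = fit_gdm(small_world_gdm["pair_table"])
        assert m1.intercept == m2.intercept
        for p in m1.coefficients:
            assert np.array_equal(m1.coefficients[p], m2.coefficients[p])

    def test_prediction_invariant_to_predictor_order(self, toy_setup):
        sites, resp, geo = toy_setup
        m1 = fit_gdm(make_pair_table(sites, ["temp", "rain"], resp, geo))
        m2 = fit_gdm(make_pair_table(sites, ["rain", "temp"], resp, geo))
        env = sites.env_values(["temp", "rain"])
        a = {p: env[p].iloc[0] for p in ["temp", "rain"]}
        b = {p: env[p].iloc[3] for p in ["temp", "rain"]}
        assert m1.predict(a, b, 100.0) == pytest.approx(m2.predict(a, b, 100.0), abs=1e-8)

    def test_adding_predictor_never_hurts_training_fit(self):
        """Nested-model property over random synthetic worlds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 10
            df = pd.DataFrame(
                {
                    "lat": rng.uniform(-38, -30, n),
                    "lon": rng.uniform(144, 152, n),
                    "e1": rng.normal(size=n),
                    "e2": rng.normal(size=n),
                },
                index=pd.Index([f"s{i}" for i in range(n)], name="site_id"),
            )
            sites = SiteTable(df)
            geo = yb.geographic_distance(sites)
            v = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            v[iu] = rng.uniform(0.05, 0.8, iu[0].size)
            v += v.T
            resp = scaled_response(sites.site_ids, v)
            de1 = fit_gdm(make_pair_table(sites, ["e1"], resp, geo)).deviance_explained
            de2 = fit_gdm(make_pair_table(sites, ["e1", "e2"], resp, geo)).deviance_explained
            assert de2 >= de1 - 1e-8


class TestPrediction:
    def test_zero_model_predicts_zero(self, toy_setup):
        sites, resp, geo = toy_setup
        zero = scaled_response(sites.site_ids, np.zeros((4, 4)))
        model = fit_gdm(make_pair_table(sites, ["temp"], zero, geo))
        assert model.predict({"temp": 12.0}, {"temp": 18.0}, 500.0) == 0.0

    def test_identical_env_zero_distance_leaves_intercept(self, small_world_gdm, small_world):
        model = small_world_gdm["model"]
        env = {p: 0.1 for p in model.predictors}
        expected = 1 - np.exp(-model.intercept)
        assert model.predict(env, env, 0.0) == pytest.approx(expected)

    def test_monotone_in_env_difference(self, small_world_gdm):
        model = small_world_gdm["model"]
        p0 = model.predictors[0]
        base = {p: 0.0 for p in model.predictors}
        rng = np.random.default_rng(7)
        for _ in range(50):
            d1, d2 = np.sort(rng.uniform(0, 3, 2))
            a = dict(base)
            b1 = dict(base, **{p0: d1})
            b2 = dict(base, **{p0: d2})
            assert model.predict(a, b2, 0.0) >= model.predict(a, b1, 0.0) - 1e-12

    def test_missing_predictor_rejected(self, small_world_gdm):
        model = small_world_gdm["model"]
        with pytest.raises(ValueError, match="missing predictor"):
            model.predict({}, {}, 0.0)

    def test_prediction_in_unit_interval(self, small_world_gdm, rng):
        model = small_world_gdm["model"]
        for _ in range(20):
            a = {p: rng.normal() for p in model.predictors}
            b = {p: rng.normal() for p in model.predictors}
            v = model.predict(a, b, rng.uniform(0, 2000))
            assert 0.0 <= v < 1.0


class TestDevianceAndCurves:
    def test_perfect_fit_explains_everything(self, toy_setup):
        sites, resp, geo = toy_setup
        pt = make_pair_table(sites, ["temp"], resp, geo)
        x = pt.design()
        mu = 1 - np.exp(-(0.05 + x @ np.full(x.shape[1], 0.3)))
        pt.df["d"] = mu
        model = fit_gdm(pt)
        assert model.deviance_explained == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only_data_explains_nothing(self, toy_setup):
        sites, resp, geo = toy_setup
        pt = make_pair_table(sites, ["temp"], resp, geo)
        pt.df["d"] = 0.4  # constant response: the null model is the best model
        model = fit_gdm(pt)
        assert model.deviance_explained == pytest.approx(0.0, abs=1e-9)

    def test_null_deviance_matches_mean_response(self):
        d = np.array([0.1, 0.3, 0.5])
        b0, dev = null_deviance(d)
        assert 1 - np.exp(-b0) == pytest.approx(d.mean())
        assert dev == pytest.approx(((d - d.mean()) ** 2).sum())

    def test_deviance_tracks_generating_r2(self, rng):
        """With known noise on 500 pairs the deviance explained lands near
        the generating signal fraction."""
        n = 500
        x = rng.uniform(0, 1, size=(n, 1))
        mu = 1 - np.exp(-(0.05 + 1.2 * x[:, 0]))
        noise = rng.normal(0, 0.05, n)
        d = np.clip(mu + noise, 0, 1)
        beta, dev, _ = fit_gdm_design(x, d)
        de = 1 - dev / ((d - d.mean()) ** 2).sum()
        r2_gen = mu.var() / (mu.var() + noise.var())
        assert de == pytest.approx(r2_gen, abs=0.05)

    def test_curves_start_at_zero_and_are_monotone(self, small_world_gdm):
        model = small_world_gdm["model"]
        curves = yb.spline_curves(model, n_points=100)
        for p, grp in curves.groupby("predictor"):
            f = grp.sort_values("x")["f"].to_numpy()
            assert f[0] == pytest.approx(0.0, abs=1e-12)
            assert np.all(np.diff(f) >= -1e-12)
            assert f[-1] == pytest.approx(model.coefficients[p].sum(), abs=1e-9)

    def test_model_json_round_trip(self, small_world_gdm):
        model = small_world_gdm["model"]
        clone = GDMModel.from_json(model.to_json())
        env_a = {p: -0.5 for p in model.predictors}
        env_b = {p: 1.2 for p in model.predictors}
        assert clone.predict(env_a, env_b, 321.0) == pytest.approx(
            model.predict(env_a, env_b, 321.0), abs=1e-12
        )
        assert clone.deviance_explained == pytest.approx(model.deviance_explained)
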