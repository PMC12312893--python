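"""Second-stage models: exposure, measurement-error regression against the
weighted-least-squares closed form, the change model and the functional
response in its three structures."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from footsel.grid import GridSpec, Raster
from footsel.habitat import sample_available
from footsel.secondstage import (
    MeasurementErrorRegression,
    compute_exposure,
    exposures_from_table,
    fit_change_model,
    fit_functional_response,
    predict_functional_response,
    quadrature_changes,
)


def _footprint_raster(values):
    values = np.asarray(values, dtype=float)
    grid = GridSpec.from_extent(values.shape[1] * 30.0, values.shape[0] * 30.0, 30.0)
    return Raster(grid, values)


class TestExposure:
    def test_constant_raster_gives_constant_exposure(self):
        fp = _footprint_raster(np.full((20, 20), 0.3))
        pts = np.random.default_rng(0).uniform(30, 570, (200, 2))
        assert compute_exposure(pts, fp) == pytest.approx(0.3)

    def test_exposure_within_cell_range(self):
        rng = np.random.default_rng(1)
        fp = _footprint_raster(rng.uniform(0, 1, (20, 20)))
        pts = rng.uniform(0, 600, (500, 2))
        e = compute_exposure(pts, fp)
        assert fp.values.min() <= e <= fp.values.max()

    def test_monte_carlo_matches_exact_cell_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, (20, 20))
        fp = _footprint_raster(vals)
        # home range aligned with whole cells: exact mean is the cell mean
        poly = box(60.0, 60.0, 540.0, 540.0)
        pts = sample_available(poly, 100, ratio=50, seed=3)  # 5000 draws
        exact = vals[2:18, 2:18].mean()
        mc = compute_exposure(pts, fp)
        tol = 3.0 * vals[2:18, 2:18].std() / np.sqrt(len(pts))
        assert abs(mc - exact) <= tol

    def test_no_points_rejected(self):
        fp = _footprint_raster(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="no available points"):
            compute_exposure(np.empty((0, 2)), fp)

    def test_exposures_from_table_uses_available_rows(self):
        table = pd.DataFrame({
            "used": [1, 0, 0, 0],
            "footprint": [0.9, 0.2, 0.4, 0.6],
            "individual_year_id": "A1_2019",
            "animal_id": "A1",
            "year": 2019,
            "population": "P1",
        })
        out = exposures_from_table(table)
        assert out.loc[0, "exposure"] == pytest.approx(0.4)


class TestMeasurementErrorRegression:
    def _data(self, n=60, sd=0.3, seed=4):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
        gamma = np.array([0.2, 3.0])
        y_sd = np.full(n, sd)
        y = X @ gamma + rng.normal(0, y_sd)
        return X, y, y_sd, gamma

    def test_flat_prior_matches_wls_closed_form(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X, y, y_sd, _ = self._data()
        y_sd = rng.uniform(0.1, 0.8, len(y))
        fit = MeasurementErrorRegression(prior_precision=0.0).fit(X, y, y_sd)
        wls = sm.WLS(y, X, weights=1.0 / y_sd**2).fit()
        np.testing.assert_allclose(fit.coef_, wls.params, atol=1e-8)

    def test_equal_sds_match_ols_to_1e6(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, y_sd, _ = self._data(sd=0.05)
        fit = MeasurementErrorRegression(prior_precision=0.0).fit(X, y, y_sd)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef_, ols.params, atol=1e-6)

    def test_doubling_sds_widens_interval(self):
        X, y, y_sd, _ = self._data()
        a = MeasurementErrorRegression().fit(X, y, y_sd).coef_summary()
        b = MeasurementErrorRegression().fit(X, y, 2 * y_sd).coef_summary()
        assert (b["sd"] > a["sd"]).all()

    def test_inflated_observation_loses_leverage(self):
        X, y, y_sd, _ = self._data(n=30)
        # make one point an outlier in y
        y2 = y.copy()
        y2[0] += 5.0
        full = MeasurementErrorRegression().fit(X, y2, y_sd).coef_[1]
        without = MeasurementErrorRegression().fit(X[1:], y2[1:], y_sd[1:]).coef_[1]
        y_sd_infl = y_sd.copy()
        y_sd_infl[0] *= 100.0
        deflated = MeasurementErrorRegression().fit(X, y2, y_sd_infl).coef_[1]
        assert abs(deflated - without) < abs(full - without)

    def test_nonpositive_sd_rejected(self):
        X, y, y_sd, _ = self._data()
        y_sd[0] = 0.0
        with pytest.raises(ValueError):
            MeasurementErrorRegression().fit(X, y, y_sd)


class TestChangeModel:
    def _obs(self, n=40, slope=3.0, noise=True, seed=6):
        rng = np.random.default_rng(seed)
        expo = rng.uniform(0, 0.6, n)
        sd = np.full(n, 0.25 if noise else 1e-4)
        delta = 0.2 + slope * expo + (rng.normal(0, sd) if noise else 0.0)
        obs = pd.DataFrame({
            "animal_id": [f"A{i}" for i in range(n)],
            "population": np.where(np.arange(n) < n // 2, "P1", "P2"),
            "delta_mean": delta,
            "delta_sd": sd,
        })
        expos = pd.DataFrame({"animal_id": obs["animal_id"], "exposure": expo})
        return obs, expos

    def test_noiseless_line_recovers_slope_within_1pc(self):
        obs, expos = self._obs(noise=False)
        fit = fit_change_model(obs, expos)
        assert fit.slope["mean"] == pytest.approx(3.0, rel=0.01)

    def test_slope_interval_covers_simulation_truth(self):
        sm = pytest.importorskip("statsmodels.api")
        obs, expos = self._obs()
        fit = fit_change_model(obs, expos)
        assert fit.slope["ci_low"] <= 3.0 <= fit.slope["ci_high"]
        # weighted-least-squares oracle agrees with the posterior mean
        X = np.column_stack([
            (obs["population"] == "P1").astype(float),
            (obs["population"] == "P2").astype(float),
            obs["animal_id"].map(dict(zip(expos["animal_id"], expos["exposure"]))),
        ])
        wls = sm.WLS(obs["delta_mean"], X, weights=1 / obs["delta_sd"]**2).fit()
        assert fit.slope["mean"] == pytest.approx(wls.params[2], abs=0.02)

    def test_unpaired_animal_rejected(self):
        obs, expos = self._obs(n=10)
        expos = expos.iloc[:-1]
        with pytest.raises(ValueError, match="without a paired"):
            fit_change_model(obs, expos)

    def test_quadrature_changes_combines_sds(self):
        coefs = pd.DataFrame({
            "animal_id": ["A1", "A1"],
            "population": ["P1", "P1"],
            "year": [2019, 2020],
            "mean": [-2.0, -1.0],
            "sd": [0.3, 0.4],
        })
        out = quadrature_changes(coefs)
        assert out.loc[0, "delta_mean"] == pytest.approx(1.0)
        assert out.loc[0, "delta_sd"] == pytest.approx(0.5)


def _fr_observations(n_per=30, slopes=(-1.0, 4.0), seed=7, n_pops=3):
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = {f"P{k}": rng.normal(-2.0, 0.5) for k in range(n_pops)}
    species = {"P0": "elk", "P1": "moose", "P2": "puma"}
    guilds = {"elk": "ungulate", "moose": "ungulate", "puma": "large carnivore"}
    for t, slope in zip((2019, 2020), slopes):
        for i in range(n_per):
            pop = f"P{i % n_pops}"
            expo = rng.uniform(0.0, 0.6)
            sd = 0.3
            rows.append({
                "individual_year_id": f"A{i}_{t}",
                "year": t,
                "population": pop,
                "species": species[pop],
                "guild": guilds[species[pop]],
                "beta_mean": intercepts[pop] + slope * expo + rng.normal(0, sd),
                "beta_sd": sd,
                "exposure": expo,
            })
    return pd.DataFrame(rows), intercepts


class TestFunctionalResponse:
    def test_opposite_year_slopes_recovered(self):
        obs, _ = _fr_observations()
        fit = fit_functional_response(obs, structure="global")
        s19 = fit.slope_summaries[("all", 2019)]
        s20 = fit.slope_summaries[("all", 2020)]
        assert s19["ci_low"] <= -1.0 <= s19["ci_high"]
        assert s20["ci_low"] <= 4.0 <= s20["ci_high"]
        assert s20["mean"] > s19["mean"]

    def test_constant_exposure_flagged_unidentifiable(self):
        obs, _ = _fr_observations()
        obs["exposure"] = 0.25
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            fit = fit_functional_response(obs, structure="global")
        assert not fit.slope_summaries[("all", 2019)]["identifiable"]

    def test_guild_model_excludes_small_carnivore(self):
        obs, _ = _fr_observations()
        fox = obs.iloc[:2].copy()
        fox["species"] = "red fox"
        fox["guild"] = "excluded"
        fit = fit_functional_response(pd.concat([obs, fox]), structure="guild")
        assert all(g in ("large carnivore", "ungulate")
                   for g, _ in fit.slope_keys)

    def test_species_model_has_species_year_slopes(self):
        obs, _ = _fr_observations()
        fit = fit_functional_response(obs, structure="species")
        assert ("elk", 2019) in fit.slope_keys
        assert ("puma", 2020) in fit.slope_keys

    def test_single_population_global_reduces_to_year_intercept_model(self):
        obs, _ = _fr_observations(n_pops=1)
        fit = fit_functional_response(obs, structure="global")
        X = np.zeros((len(obs), 4))
        X[:, 0] = (obs["year"] == 2019).astype(float)
        X[:, 1] = (obs["year"] == 2020).astype(float)
        X[:, 2] = np.where(obs["year"] == 2019, obs["exposure"], 0.0)
        X[:, 3] = np.where(obs["year"] == 2020, obs["exposure"], 0.0)
        direct = MeasurementErrorRegression().fit(
            X, obs["beta_mean"].to_numpy(), obs["beta_sd"].to_numpy())
        assert fit.slope_summaries[("all", 2019)]["mean"] == pytest.approx(
            direct.coef_[2], abs=1e-9)

    def test_unknown_structure_rejected(self):
        obs, _ = _fr_observations()
        with pytest.raises(ValueError):
            fit_functional_response(obs, structure="family")


class TestPredictFunctionalResponse:
    @pytest.fixture(scope="class")
    def fit(self):
        obs, _ = _fr_observations()
        return fit_functional_response(obs, structure="global")

    def test_prediction_at_zero_equals_intercept(self, fit):
        pred = predict_functional_response(fit, [0.0], year=2019, unit="P1")
        col = fit.intercept_keys[("P1", 2019)]
        draws = fit.model.draws_[:, col]
        assert pred.loc[0, "mean"] == pytest.approx(draws.mean())

    def test_band_widens_away_from_exposure_mean(self, fit):
        grid = np.linspace(0.0, 0.6, 7)
        pred = predict_functional_response(fit, grid, year=2020, unit="P1")
        width = pred["ci_high"] - pred["ci_low"]
        assert width.iloc[-1] > width.iloc[len(grid) // 2 - 1]

    def test_curve_is_drawwise_linear(self, fit):
        pred = predict_functional_response(fit, [0.1, 0.5], year=2019, unit="P0")
        slope_draws = fit.model.draws_[:, fit.slope_keys[("all", 2019)]]
        assert pred["mean"].diff().iloc[1] == pytest.approx(
            0.4 * slope_draws.mean(), abs=1e-9)

    def test_unknown_group_rejected(self, fit):
        with pytest.raises(KeyError):
            predict_functional_response(fit, [0.1], year=2019, group="ungulate")

    def test_extrapolation_flagged(self, fit):
        with pytest.warns(RuntimeWarning, match="beyond the observed"):
            pred = predict_functional_response(fit, [0.9], year=2019, unit="P0")
        assert pred.loc[0, "extrapolated"]
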