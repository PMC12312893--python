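"""Second-stage models: exposure, individual change, functional response.

First-stage posterior means of the footprint selection coefficient are
treated as observations with known, observation-specific measurement
precision tau_j = 1 / sd_j^2.  With normal priors on the regression
coefficients the posterior is Gaussian in closed form, so these fits are
exact conjugate computations (draws are taken from the analytic posterior
for interval summaries); tests cross-check the point estimates against
closed-form weighted least squares.

Three structures mirror the study design:

* change model - response is each twice-tracked animal's 2020 - 2019 change
  in footprint coefficient, predictor its 2019 exposure, one intercept per
  population, one common slope;
* global functional response - response is every individual-year coefficient,
  intercept per population-year, one slope per year;
* guild / species models - slopes (and for species, intercepts) vary by
  guild-year or species-year; the "excluded" guild (the lone small
  carnivore) is dropped from the guild model.

Exposure is the mean footprint over the available points of the
individual-year's 95% KUD home range, computed once from the used/available
table so both second-stage models see identical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grid import Raster


# ---------------------------------------------------------------- exposure

def compute_exposure(points: np.ndarray, footprint: Raster) -> float:
    """Mean footprint at an individual-year's available points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("no available points for exposure computation")
    return float(footprint.extract(pts[:, 0], pts[:, 1]).mean())


def exposures_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Exposure per individual-year from the used/available table's
    available rows (the single source of truth for both second-stage models)."""
    avail = table[table["used"] == 0]
    rows = []
    for key, grp in avail.groupby("individual_year_id", sort=False):
        rows.append({
            "individual_year_id": key,
            "animal_id": grp["animal_id"].iloc[0],
            "year": int(grp["year"].iloc[0]),
            "population": grp["population"].iloc[0],
            "exposure": float(grp["footprint"].mean()),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------- measurement-error core

class MeasurementErrorRegression(BaseEstimator):
    """Bayesian linear regression with known per-observation noise sd.

    Model: y_j ~ Normal(x_j' gamma, sd_j^2 (+ residual_sd^2)), priors
    gamma ~ Normal(0, prior_precision^-1 I).  The posterior is Gaussian and
    computed exactly; ``prior_precision=0`` gives the flat-prior limit
    (= weighted least squares), in which case the design must be full rank.

    Attributes
    ----------
    coef_ : posterior mean
    coef_cov_ : posterior covariance
    draws_ : (n_draws, p) samples from the posterior
    """

    def __init__(self, prior_precision: float = 0.01, residual_sd: float = 0.0,
                 n_draws: int = 4000, random_state: int = 0):
        self.prior_precision = prior_precision
        self.residual_sd = residual_sd
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X, y, y_sd):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        y_sd = np.asarray(y_sd, dtype=float)
        if np.any(y_sd <= 0):
            raise ValueError("measurement sds must be strictly positive")
        w = 1.0 / (y_sd**2 + self.residual_sd**2)
        P = self.prior_precision * np.eye(X.shape[1]) + (X * w[:, None]).T @ X
        if self.prior_precision == 0 and np.linalg.matrix_rank(P) < X.shape[1]:
            raise ValueError("flat-prior fit requires a full-rank design")
        V = np.linalg.inv(P)
        V = 0.5 * (V + V.T)
        m = V @ (X.T @ (w * y))
        rng = np.random.default_rng(self.random_state)
        self.coef_ = m
        self.coef_cov_ = V
        self.draws_ = rng.multivariate_normal(m, V, size=self.n_draws,
                                              method="cholesky")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_

    def coef_summary(self) -> pd.DataFrame:
        q = np.percentile(self.draws_, [2.5, 97.5], axis=0)
        return pd.DataFrame({"mean": self.coef_, "sd": np.sqrt(np.diag(self.coef_cov_)),
                             "q2.5": q[0], "q97.5": q[1]})


def _summary_for(draws: np.ndarray, mean: float | None = None,
                 sd: float | None = None) -> dict:
    """Posterior summary: exact moments when supplied (the posterior is
    Gaussian in closed form), equal-tailed interval from the draws."""
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": float(draws.mean()) if mean is None else float(mean),
        "sd": float(draws.std(ddof=1)) if sd is None else float(sd),
        "ci_low": float(lo), "ci_high": float(hi),
    }


# --------------------------------------------------------- change model

@dataclass
class ChangeModelFit:
    model: MeasurementErrorRegression
    columns: list[str]
    slope: dict
    intercepts: dict[str, dict]
    observations: pd.DataFrame


def fit_change_model(
    observations: pd.DataFrame,
    exposures_2019: pd.DataFrame | dict,
    prior_precision: float = 0.01,
    random_state: int = 0,
) -> ChangeModelFit:
    """Individual change in footprint selection against 2019 exposure.

    ``observations`` needs one row per twice-tracked animal with columns
    animal_id, population, delta_mean, delta_sd (the draw-wise 2020 - 2019
    posterior difference; if only per-year summaries exist, combine the sds
    in quadrature beforehand).  Any animal without an exposure entry is a
    pairing error and rejected.
    """
    obs = observations.copy()
    if isinstance(exposures_2019, pd.DataFrame):
        expo = dict(zip(exposures_2019["animal_id"], exposures_2019["exposure"]))
    else:
        expo = dict(exposures_2019)
    missing = [a for a in obs["animal_id"] if a not in expo]
    if missing:
        raise ValueError(f"animals without a paired 2019 exposure: {missing}")
    if obs["animal_id"].duplicated().any():
        raise ValueError("duplicate animal in change-model observations")
    obs["exposure"] = obs["animal_id"].map(expo)

    pops = list(pd.unique(obs["population"]))
    X = np.zeros((len(obs), len(pops) + 1))
    for i, p in enumerate(pops):
        X[:, i] = (obs["population"] == p).to_numpy(float)
    X[:, -1] = obs["exposure"].to_numpy(float)
    cols = [f"intercept[{p}]" for p in pops] + ["slope"]

    model = MeasurementErrorRegression(
        prior_precision=prior_precision, random_state=random_state
    ).fit(X, obs["delta_mean"].to_numpy(float), obs["delta_sd"].to_numpy(float))
    sds = np.sqrt(np.diag(model.coef_cov_))
    return ChangeModelFit(
        model=model,
        columns=cols,
        slope=_summary_for(model.draws_[:, -1], model.coef_[-1], sds[-1]),
        intercepts={p: _summary_for(model.draws_[:, i], model.coef_[i], sds[i])
                    for i, p in enumerate(pops)},
        observations=obs,
    )


def quadrature_changes(coefs: pd.DataFrame) -> pd.DataFrame:
    """Fallback change observations from per-year coefficient summaries:
    delta = mean_2020 - mean_2019, sd = sqrt(sd19^2 + sd20^2)."""
    wide = coefs.pivot_table(index=["animal_id", "population"], columns="year",
                             values=["mean", "sd"], aggfunc="first")
    wide = wide.dropna()
    out = pd.DataFrame({
        "animal_id": [a for a, _ in wide.index],
        "population": [p for _, p in wide.index],
        "delta_mean": (wide[("mean", 2020)] - wide[("mean", 2019)]).to_numpy(),
        "delta_sd": np.hypot(wide[("sd", 2019)], wide[("sd", 2020)]).to_numpy(),
    })
    return out.reset_index(drop=True)


# ------------------------------------------------- functional response

@dataclass
class FunctionalResponseFit:
    structure: str                       # global | guild | species
    model: MeasurementErrorRegression
    columns: list[str]
    slope_keys: dict[tuple, int]         # (group, year) -> design column
    intercept_keys: dict[tuple, int]     # (unit, year) -> design column
    slope_summaries: dict[tuple, dict]
    flagged: list[tuple] = field(default_factory=list)
    exposure_range: tuple[float, float] = (0.0, 1.0)
    observations: pd.DataFrame | None = None

    def slope_draws(self, group, year) -> np.ndarray:
        key = (group, int(year))
        if key not in self.slope_keys:
            raise KeyError(f"no slope for group/year {key}")
        return self.model.draws_[:, self.slope_keys[key]]


def fit_functional_response(
    observations: pd.DataFrame,
    structure: str = "global",
    prior_precision: float = 0.01,
    random_state: int = 0,
) -> FunctionalResponseFit:
    """Exposure-mediated functional response of footprint selection.

    ``observations`` has one row per individual-year: individual_year_id,
    year, population, species, guild, beta_mean, beta_sd, exposure.  The
    response is beta_mean with measurement precision 1/beta_sd^2; intercepts
    are population-year (global, guild) or species-year (species); slopes are
    per year (global), per guild-year (guild) or per species-year (species).
    Slope groups with fewer than two observations, or without exposure
    variation, are flagged unidentifiable (the posterior reverts to the
    prior for them).
    """
    if structure not in ("global", "guild", "species"):
        raise ValueError(f"unknown structure {structure!r}")
    obs = observations.copy()
    if structure == "guild":
        obs = obs[obs["guild"] != "excluded"].copy()
        bad = set(obs["guild"]) - {"large carnivore", "ungulate"}
        if bad:
            raise ValueError(f"unknown guilds {sorted(bad)}")

    unit_col = "species" if structure == "species" else "population"
    if structure == "global":
        group_col = None
    elif structure == "guild":
        group_col = "guild"
    else:
        group_col = "species"

    obs["year"] = obs["year"].astype(int)
    intercept_units = list(dict.fromkeys(zip(obs[unit_col], obs["year"])))
    if group_col is None:
        slope_groups = [("all", y) for y in sorted(obs["year"].unique())]
        obs["_grp"] = "all"
    else:
        obs["_grp"] = obs[group_col]
        slope_groups = list(dict.fromkeys(zip(obs["_grp"], obs["year"])))

    n = len(obs)
    X = np.zeros((n, len(intercept_units) + len(slope_groups)))
    cols: list[str] = []
    intercept_keys: dict[tuple, int] = {}
    for i, (u, y) in enumerate(intercept_units):
        X[:, i] = ((obs[unit_col] == u) & (obs["year"] == y)).to_numpy(float)
        cols.append(f"intercept[{u},{y}]")
        intercept_keys[(u, int(y))] = i
    slope_keys: dict[tuple, int] = {}
    flagged: list[tuple] = []
    off = len(intercept_units)
    for i, (g, y) in enumerate(slope_groups):
        sel = ((obs["_grp"] == g) & (obs["year"] == y)).to_numpy()
        X[sel, off + i] = obs.loc[sel, "exposure"].to_numpy(float)
        cols.append(f"slope[{g},{y}]")
        slope_keys[(g, int(y))] = off + i
        # identifiable only with >= 2 obs and exposure variation net of
        # the intercept structure
        if sel.sum() < 2:
            flagged.append((g, int(y)))
            continue
        sub = obs.loc[sel]
        resid = sub["exposure"] - sub.groupby(unit_col)["exposure"].transform("mean")
        if float((resid**2).sum()) < 1e-12:
            flagged.append((g, int(y)))
    if flagged and prior_precision == 0:
        raise ValueError(f"unidentifiable slopes with a flat prior: {flagged}")
    if flagged:
        warnings.warn(f"unidentifiable functional-response slopes: {flagged}",
                      RuntimeWarning)

    model = MeasurementErrorRegression(
        prior_precision=prior_precision, random_state=random_state
    ).fit(X, obs["beta_mean"].to_numpy(float), obs["beta_sd"].to_numpy(float))

    sds = np.sqrt(np.diag(model.coef_cov_))
    summaries = {}
    for key, col in slope_keys.items():
        s = _summary_for(model.draws_[:, col], model.coef_[col], sds[col])
        s["identifiable"] = key not in flagged
        summaries[key] = s
    return FunctionalResponseFit(
        structure=structure,
        model=model,
        columns=cols,
        slope_keys=slope_keys,
        intercept_keys=intercept_keys,
        slope_summaries=summaries,
        flagged=flagged,
        exposure_range=(float(obs["exposure"].min()), float(obs["exposure"].max())),
        observations=obs,
    )


def predict_functional_response(
    fit: FunctionalResponseFit,
    exposure_grid,
    year: int,
    group: str = "all",
    unit: str | None = None,
) -> pd.DataFrame:
    """Predicted selection curve with 95% credible band.

    ``unit`` selects a specific intercept (population or species); when None
    the intercept draws of all units in that year (and, for grouped
    structures, belonging to the group) are averaged draw-wise, matching the
    "average intercept" presentation of functional-response curves.  Grid
    points outside the fitted exposure range are flagged as extrapolation.
    """
    grid = np.asarray(exposure_grid, dtype=float)
    slope = fit.slope_draws(group, year)

    if unit is not None:
        key = (unit, int(year))
        if key not in fit.intercept_keys:
            raise KeyError(f"no intercept for unit/year {key}")
        intercept = fit.model.draws_[:, fit.intercept_keys[key]]
    else:
        cols = []
        for (u, y), c in fit.intercept_keys.items():
            if y != int(year):
                continue
            if group != "all" and fit.observations is not None:
                m = (fit.observations["_grp"] == group) & (fit.observations["year"] == y)
                units = set(fit.observations.loc[m, "species" if fit.structure == "species"
                                                 else "population"])
                if u not in units:
                    continue
            cols.append(c)
        if not cols:
            raise KeyError(f"no intercepts for year {year} / group {group!r}")
        intercept = fit.model.draws_[:, cols].mean(axis=1)

    curves = intercept[:, None] + slope[:, None] * grid[None, :]
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    extrapolated = (grid < fit.exposure_range[0]) | (grid > fit.exposure_range[1])
    if extrapolated.any():
        warnings.warn("prediction grid extends beyond the observed exposure range",
                      RuntimeWarning)
    return pd.DataFrame({"exposure": grid, "mean": curves.mean(axis=0),
                         "ci_low": lo, "ci_high": hi,
                         "extrapolated": extrapolated})
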