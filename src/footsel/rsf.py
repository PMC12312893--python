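"""Hierarchical Bayesian resource selection function.

One model per population (park-species).  Each individual-year j has a
coefficient vector beta_j = (intercept, footprint, elevation, slope, five
land-cover proximities) entering a Bernoulli-logit likelihood over its
used/available rows:

    used_i ~ Bern(p_i),
    logit(p_i) = beta_intercept[j] + beta_footprint[j] * footprint_i + ...

Individual coefficients are drawn from population hyperdistributions:
scalar coefficients beta_jk ~ Normal(mu_k, tau_k) with precision tau_k; the
five land-cover coefficients jointly follow a multivariate normal with a
Wishart-prior precision matrix.  Land-cover coefficients only enter the
likelihood for individuals whose home range contains that cover type
(presence indicators multiply the contribution).

Priors (hyperparameters): mu ~ Normal(0, precision 0.01); the intercept's
between-individual sd ~ Uniform(0, 100) (transformed to precision); the
footprint/elevation/slope precisions ~ Uniform(0, 25); the land-cover
precision matrix ~ Wishart(identity scale, 6 df).

Sampling is Metropolis-within-Gibbs: blocked random-walk Metropolis on each
individual's coefficient vector (proposal covariance from a per-individual
Laplace approximation, scale adapted during burn-in), with conjugate Gibbs
updates for the hyper-means, truncated-gamma updates for the scalar
precisions and a conjugate Wishart update for the land-cover precision
matrix.  The sampler targets exactly the stated model; any sampler with the
same stationary distribution would be interchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .terms import COEF_NAMES, INDICATOR_COLUMNS, LANDCOVER_CLASSES, SCALAR_COEFS

_P = len(COEF_NAMES)          # 9 coefficients per individual-year
_LC = slice(4, _P)            # land-cover block
_NSCALAR = len(SCALAR_COEFS)  # 4 scalar hyper-precisions
_TRIU = np.triu_indices(5)


def rsf_log_likelihood(beta, X, y) -> float:
    """Bernoulli-logit log likelihood, stable for |linear predictor| ~ 700."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate in design matrix")
    if not np.isfinite(beta).all():
        raise ValueError("non-finite coefficient")
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors of the hierarchical RSF."""

    mean_precision: float = 0.01       # Normal(0, prec) on every mu
    intercept_sd_upper: float = 100.0  # Uniform(0, upper) on intercept sd
    scalar_tau_upper: float = 25.0     # Uniform(0, upper) on tau for
                                       # footprint / elevation / slope
    wishart_df: float = 6.0            # df of the land-cover precision prior
    wishart_scale: np.ndarray | None = None  # scale matrix; None -> identity

    def __post_init__(self) -> None:
        if self.wishart_df <= 5:
            raise ValueError("wishart_df must exceed the dimension (5)")
        for v in (self.mean_precision, self.intercept_sd_upper, self.scalar_tau_upper):
            if v <= 0:
                raise ValueError("prior hyperparameters must be positive")

    def widened(self, factor: float) -> "PriorSpec":
        """Widen every prior support by ``factor`` (for near-flat fits)."""
        return replace(
            self,
            mean_precision=self.mean_precision / factor**2,
            intercept_sd_upper=self.intercept_sd_upper * factor,
            scalar_tau_upper=self.scalar_tau_upper * factor,
        )

    @property
    def scale_matrix(self) -> np.ndarray:
        return np.eye(5) if self.wishart_scale is None else np.asarray(self.wishart_scale)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  Defaults are a sized-down configuration for desk-scale
    fits; :func:`published_mcmc_config` returns the full published settings."""

    n_chains: int = 3
    n_iterations: int = 3000
    burn_in: int = 1200
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iterations - burn_in) must be divisible by thin")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


def published_mcmc_config(seed: int = 0) -> MCMCConfig:
    """Published settings: 3 chains x 30000 iterations, 3000 burn-in, thin 3."""
    return MCMCConfig(n_chains=3, n_iterations=30000, burn_in=3000, thin=3, seed=seed)


@dataclass
class RSFPosterior:
    """Posterior draws and bookkeeping for one population's RSF."""

    draws: np.ndarray                 # (chains, draws, n_params)
    param_names: list[str]
    groups: pd.DataFrame              # individual_year_id, animal_id, year, population
    indicators: pd.DataFrame          # per-group land-cover presence (0/1)
    mcmc: MCMCConfig
    priors: PriorSpec
    max_rhat: float | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.param_names)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def draws_for(self, name: str) -> np.ndarray:
        """(chains, draws) array for one named parameter."""
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.draws_for(name).ravel()

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        q = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "parameter": self.param_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[1],
        })

    def individual_coefficients(self, coef: str = "footprint") -> pd.DataFrame:
        """Posterior mean/sd of one coefficient for every individual-year."""
        rows = []
        for _, g in self.groups.iterrows():
            d = self.flat(f"beta[{g.individual_year_id}].{coef}")
            rows.append({
                "individual_year_id": g.individual_year_id,
                "animal_id": g.animal_id,
                "year": g.year,
                "population": g.population,
                "mean": d.mean(),
                "sd": d.std(ddof=1),
            })
        return pd.DataFrame(rows)

    def footprint_change_draws(self) -> pd.DataFrame:
        """Draw-wise 2020 - 2019 footprint-coefficient change per animal
        tracked in both years (posterior mean and sd of the difference)."""
        byyear = {(g.animal_id, g.year): g.individual_year_id
                  for _, g in self.groups.iterrows()}
        animals = sorted({a for (a, _) in byyear})
        rows = []
        for a in animals:
            j19, j20 = byyear.get((a, 2019)), byyear.get((a, 2020))
            if j19 is None or j20 is None:
                continue
            delta = (self.flat(f"beta[{j20}].footprint")
                     - self.flat(f"beta[{j19}].footprint"))
            rows.append({"animal_id": a, "delta_mean": delta.mean(),
                         "delta_sd": delta.std(ddof=1)})
        return pd.DataFrame(rows)


def _laplace_proposal(X, y, masked, ridge: float = 1e-4):
    """Penalised MLE and a Laplace proposal Cholesky for one individual."""
    n, p = X.shape

    def negll(b):
        eta = X @ b
        return np.logaddexp(0.0, eta).sum() - y @ eta + 0.5 * ridge * b @ b

    def grad(b):
        eta = X @ b
        return X.T @ (special.expit(eta) - y) + ridge * b

    res = optimize.minimize(negll, np.zeros(p), jac=grad, method="L-BFGS-B")
    bhat = res.x
    w = special.expit(X @ bhat)
    # floor the information eigenvalues at 1: directions the data barely
    # identify (near-constant covariates, masked land-cover terms) fall back
    # to a proposal scale of order the hyperprior, while well-identified
    # correlated ridges (e.g. intercept vs a high-mean covariate) keep their
    # exact geometry
    H = X.T @ (X * (w * (1.0 - w))[:, None]) + ridge * np.eye(p)
    evals, evecs = np.linalg.eigh(0.5 * (H + H.T))
    cov = (evecs / np.maximum(evals, 1.0)) @ evecs.T
    L = np.linalg.cholesky(cov * (2.38**2 / p))
    return bhat, cov, L


def _truncated_gamma(rng, shape_a, rate, lower=0.0, upper=np.inf):
    """Draw from Gamma(shape, rate) truncated to (lower, upper)."""
    scale = 1.0 / rate if rate > 0 else np.inf
    if not np.isfinite(scale):
        # flat in the exponential term: power-law density tau^(shape-1)
        u = rng.uniform()
        hi = upper if np.isfinite(upper) else 1.0
        return hi * u ** (1.0 / shape_a)
    flo = stats.gamma.cdf(lower, shape_a, scale=scale) if lower > 0 else 0.0
    fhi = stats.gamma.cdf(upper, shape_a, scale=scale) if np.isfinite(upper) else 1.0
    if fhi - flo < 1e-12:
        # numerically degenerate: nearly all mass outside the interval
        if fhi < 1e-12 and np.isfinite(upper):
            # mass above the cap; density ~ tau^(shape-1) over (lower, upper)
            u = rng.uniform()
            return lower + (upper - lower) * u ** (1.0 / shape_a)
        return max(lower, min(upper, shape_a * scale))
    u = rng.uniform(flo, fhi)
    return float(stats.gamma.ppf(u, shape_a, scale=scale))


def _ll_from_eta(eta, y) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _prior_logpdf(beta, mu, tau_scalar, lam):
    d = beta[:_NSCALAR] - mu[:_NSCALAR]
    lp = -0.5 * np.sum(tau_scalar * d * d)
    dl = beta[_LC] - mu[_LC]
    lp -= 0.5 * dl @ lam @ dl
    return lp


def _run_chain(chain_seed, Xs, ys, masks, priors, mcmc, proposals, pooled_cov):
    rng = np.random.default_rng(chain_seed)
    J = len(Xs)
    p0 = priors.mean_precision
    v0_inv = np.linalg.inv(priors.scale_matrix)

    # --- overdispersed initial state around empirically shrunk Laplace fits.
    # Barely identified coordinates have wild MLEs; initialising them at the
    # information-weighted pooled mean keeps early iterations in plausible
    # mass (initialisation only - the target distribution is unchanged).
    bhats = np.stack([p[0] for p in proposals])
    infos = np.stack([1.0 / np.maximum(np.diag(p[1]), 1e-12) for p in proposals])
    w = infos / (infos + 1.0)
    pooled_mean = (w * bhats).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
    shrunk = w * bhats + (1.0 - w) * pooled_mean
    betas = shrunk + rng.normal(size=(J, _P)) * np.minimum(
        np.sqrt(1.0 / infos), 1.0)
    mu = pooled_mean + rng.normal(scale=0.1, size=_P)
    if J > 1:
        v = shrunk.var(axis=0, ddof=1) + 0.05
    else:
        v = np.ones(_P)
    tau_scalar = np.clip(1.0 / v[:_NSCALAR], 0.05, None)
    tau_scalar *= np.exp(rng.normal(scale=0.2, size=_NSCALAR))
    tau_scalar[1:] = np.minimum(tau_scalar[1:], 0.9 * priors.scalar_tau_upper)
    lam = np.eye(5) * np.exp(rng.normal(scale=0.2))

    etas = [Xs[j] @ betas[j] for j in range(J)]
    loglik = np.array([_ll_from_eta(etas[j], ys[j]) for j in range(J)])
    log_scale = np.zeros(J)
    log_tscale = 0.5 * np.log(np.diag(pooled_cov) + 1e-8)
    tau_int_min = 1.0 / priors.intercept_sd_upper**2
    log_tau_int = np.log(max(1.0 / v[0], tau_int_min * 10))

    n_params = J * _P + _P + _NSCALAR + len(_TRIU[0])
    out = np.empty((mcmc.n_draws, n_params))
    k_out = 0

    for it in range(mcmc.n_iterations):
        # --- blocked Metropolis update of each individual's coefficients
        for _sweep in range(2):
            for j in range(J):
                _, _, L = proposals[j]
                prop = betas[j] + np.exp(log_scale[j]) * (L @ rng.normal(size=_P))
                eta_prop = Xs[j] @ prop
                ll_prop = _ll_from_eta(eta_prop, ys[j])
                la = (ll_prop + _prior_logpdf(prop, mu, tau_scalar, lam)
                      - loglik[j] - _prior_logpdf(betas[j], mu, tau_scalar, lam))
                alpha = min(1.0, np.exp(min(la, 0.0)))
                if rng.uniform() < alpha:
                    betas[j] = prop
                    etas[j] = eta_prop
                    loglik[j] = ll_prop
                if it < mcmc.burn_in:
                    log_scale[j] += (it + 1) ** -0.6 * (alpha - 0.234)

        # --- per-coefficient translation of (mu_k, all beta_jk): shifts the
        # population level of one coefficient at a time, decorrelating it
        # from the hierarchy (interweaving-style update); the beta|mu prior
        # terms cancel, only the likelihoods and the mu prior change
        for k in range(_P):
            delta = np.exp(log_tscale[k]) * rng.normal()
            new_etas = [etas[j] + delta * Xs[j][:, k] for j in range(J)]
            new_ll = np.array([_ll_from_eta(new_etas[j], ys[j]) for j in range(J)])
            mu_k_new = mu[k] + delta
            la = (new_ll.sum() - loglik.sum()
                  - 0.5 * p0 * (mu_k_new**2 - mu[k] ** 2))
            alpha = min(1.0, np.exp(min(la, 0.0)))
            if rng.uniform() < alpha:
                betas[:, k] += delta
                mu[k] = mu_k_new
                etas = new_etas
                loglik = new_ll
            if it < mcmc.burn_in:
                log_tscale[k] += (it + 1) ** -0.6 * (alpha - 0.44)

        # --- conjugate updates of the hyper-means
        for k in range(_NSCALAR):
            prec = p0 + J * tau_scalar[k]
            mean = tau_scalar[k] * betas[:, k].sum() / prec
            mu[k] = mean + rng.normal() / np.sqrt(prec)
        P_lc = p0 * np.eye(5) + J * lam
        cF = np.linalg.cholesky(P_lc)
        m_lc = np.linalg.solve(P_lc, lam @ betas[:, _LC].sum(axis=0))
        mu[_LC] = m_lc + np.linalg.solve(cF.T, rng.normal(size=5))

        # --- scalar precisions
        s_int = np.sum((betas[:, 0] - mu[0]) ** 2)
        if J >= 2:
            tau_scalar[0] = _truncated_gamma(
                rng, (J - 1) / 2.0, s_int / 2.0, lower=tau_int_min)
        else:
            # J = 1: posterior ~ tau^(-1) exp(-tau s/2) on (tau_min, inf);
            # random-walk Metropolis on log(tau)
            prop_lt = log_tau_int + rng.normal(scale=1.0)
            if prop_lt >= np.log(tau_int_min):
                cur, prp = np.exp(log_tau_int), np.exp(prop_lt)
                la = (J / 2.0) * (prop_lt - log_tau_int) - (prp - cur) * s_int / 2.0
                if np.log(rng.uniform()) < la:
                    log_tau_int = prop_lt
            tau_scalar[0] = np.exp(log_tau_int)
        for k in range(1, _NSCALAR):
            s = np.sum((betas[:, k] - mu[k]) ** 2)
            tau_scalar[k] = _truncated_gamma(
                rng, J / 2.0 + 1.0, s / 2.0, upper=priors.scalar_tau_upper)

        # --- conjugate Wishart update of the land-cover precision matrix
        dev = betas[:, _LC] - mu[_LC]
        s_lc = dev.T @ dev
        scale_n = np.linalg.inv(v0_inv + s_lc)
        scale_n = 0.5 * (scale_n + scale_n.T)
        lam = stats.wishart.rvs(df=priors.wishart_df + J, scale=scale_n,
                                random_state=rng)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out[k_out, :J * _P] = betas.ravel()
            out[k_out, J * _P:J * _P + _P] = mu
            out[k_out, J * _P + _P:J * _P + _P + _NSCALAR] = tau_scalar
            out[k_out, J * _P + _P + _NSCALAR:] = lam[_TRIU]
            k_out += 1

    assert k_out == mcmc.n_draws
    return out


def _design_for_group(grp: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix, response and land-cover mask for one individual-year."""
    n = len(grp)
    X = np.empty((n, _P))
    X[:, 0] = 1.0
    X[:, 1] = grp["footprint"].to_numpy(float)
    X[:, 2] = grp["elevation"].to_numpy(float)
    X[:, 3] = grp["slope"].to_numpy(float)
    mask = np.zeros(_P, dtype=bool)
    for i, cls in enumerate(LANDCOVER_CLASSES):
        ind = int(grp[f"ind_{cls}"].iloc[0])
        X[:, 4 + i] = ind * grp[cls].to_numpy(float)
        mask[4 + i] = ind == 0
    y = grp["used"].to_numpy(float)
    return X, y, mask


def fit_hierarchical_rsf(
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> RSFPosterior:
    """Fit the hierarchical RSF to one population's used/available table."""
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    required = {"used", "individual_year_id", *COEF_NAMES[1:], *INDICATOR_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"used/available table lacks columns {sorted(missing)}")

    keys, Xs, ys, masks, meta, indic = [], [], [], [], [], []
    for key, grp in table.groupby("individual_year_id", sort=False):
        X, y, mask = _design_for_group(grp)
        keys.append(key)
        Xs.append(X)
        ys.append(y)
        masks.append(mask)
        meta.append({
            "individual_year_id": key,
            "animal_id": grp["animal_id"].iloc[0] if "animal_id" in grp else key,
            "year": int(grp["year"].iloc[0]) if "year" in grp else -1,
            "population": grp["population"].iloc[0] if "population" in grp else "P1",
        })
        indic.append({c: int(grp[c].iloc[0]) for c in INDICATOR_COLUMNS})

    proposals = [_laplace_proposal(X, y, m) for X, y, m in zip(Xs, ys, masks)]
    pooled_prec = sum(np.linalg.inv(cov) for _, cov, _ in proposals)
    pooled_cov = np.linalg.inv(pooled_prec)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [_run_chain(s, Xs, ys, masks, priors, mcmc, proposals, pooled_cov)
              for s in seeds]
    draws = np.stack(chains)

    names = [f"beta[{k}].{c}" for k in keys for c in COEF_NAMES]
    names += [f"mu.{c}" for c in COEF_NAMES]
    names += [f"tau.{c}" for c in SCALAR_COEFS]
    names += [f"lc_prec[{a},{b}]" for a, b in zip(*_TRIU)]

    post = RSFPosterior(
        draws=draws,
        param_names=names,
        groups=pd.DataFrame(meta),
        indicators=pd.DataFrame(indic, index=keys),
        mcmc=mcmc,
        priors=priors,
    )
    report = check_convergence(post)
    post.max_rhat = report.max_rhat
    post.converged = report.passed
    if not report.passed:
        warnings.warn(
            f"hierarchical RSF not converged: max R-hat = {report.max_rhat:.3f}",
            RuntimeWarning,
        )
    return post


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    max_rhat: float
    passed: bool
    threshold: float = 1.1


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin R-hat.

    ``chains`` is (n_chains, n_draws) or (n_chains, n_draws, n_params); each
    chain is split in half, then the classic between/within variance ratio is
    computed over the 2 x n_chains half-chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    c, d, p = x.shape
    if c < 2:
        raise ValueError("need at least 2 chains for R-hat")
    half = d // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    x = x[:, : 2 * half].reshape(c * 2, half, p)
    means = x.mean(axis=1)
    within = x.var(axis=1, ddof=1).mean(axis=0)
    between = half * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (half - 1) / half * within + between / half
        rhat = np.sqrt(var_plus / within)
    rhat = np.where(within == 0, np.where(between == 0, 1.0, np.inf), rhat)
    return rhat if p > 1 else rhat.reshape(())


def check_convergence(posterior: RSFPosterior, threshold: float = 1.1) -> ConvergenceReport:
    """Per-parameter split R-hat; overall pass iff max <= threshold."""
    rhat = gelman_rubin(posterior.draws)
    rhat = np.atleast_1d(rhat)
    report = ConvergenceReport(
        rhat=dict(zip(posterior.param_names, map(float, rhat))),
        max_rhat=float(np.max(rhat)),
        passed=bool(np.max(rhat) <= threshold),
        threshold=threshold,
    )
    return report


def derive_population_summaries(
    posterior: RSFPosterior, coef: str = "footprint"
) -> dict:
    """Per-year population mean of one coefficient, and the 2020 - 2019
    difference, all computed draw-wise before summarising.

    The per-year mean averages the individual-year coefficients of that
    year's animals draw by draw (the "average over individuals" aggregation);
    the hyper-mean ``mu`` is reported separately in the posterior summary.
    """
    years = sorted(posterior.groups["year"].unique())
    out: dict = {}
    year_draws: dict[int, np.ndarray] = {}
    for yr in years:
        keys = posterior.groups.loc[posterior.groups["year"] == yr,
                                    "individual_year_id"]
        stack = np.stack([posterior.flat(f"beta[{k}].{coef}") for k in keys])
        d = stack.mean(axis=0)
        year_draws[yr] = d
        lo, hi = np.percentile(d, [2.5, 97.5])
        out[yr] = {"mean": float(d.mean()), "ci_low": float(lo), "ci_high": float(hi)}
    if 2019 in year_draws and 2020 in year_draws:
        diff = year_draws[2020] - year_draws[2019]
        lo, hi = np.percentile(diff, [2.5, 97.5])
        out["difference"] = {"mean": float(diff.mean()),
                             "ci_low": float(lo), "ci_high": float(hi)}
    return out


def pool_year_summaries(
    posteriors: list[RSFPosterior], coef: str = "footprint",
    how: str = "individuals",
) -> dict:
    """Cross-population per-year means of one coefficient.

    ``how="individuals"`` averages every individual-year draw-wise (each
    animal counts once); ``how="populations"`` first averages within each
    population, then averages the population means (each population counts
    once).  The two aggregations differ whenever population sizes do, and
    both are legitimate summaries of "the average response".
    """
    if how not in ("individuals", "populations"):
        raise ValueError(f"unknown aggregation {how!r}")
    years = sorted({int(y) for p in posteriors for y in p.groups["year"]})
    out: dict = {}
    for yr in years:
        per_pop = []
        for post in posteriors:
            keys = post.groups.loc[post.groups["year"] == yr, "individual_year_id"]
            if keys.empty:
                continue
            stack = np.stack([post.flat(f"beta[{k}].{coef}") for k in keys])
            per_pop.append(stack if how == "individuals" else
                           stack.mean(axis=0, keepdims=True))
        n = min(s.shape[1] for s in per_pop)
        pooled = np.concatenate([s[:, :n] for s in per_pop]).mean(axis=0)
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        out[yr] = {"mean": float(pooled.mean()), "ci_low": float(lo),
                   "ci_high": float(hi)}
    return out


def classify_selection(mean: float, ci_low: float, ci_high: float) -> str:
    """avoid / select / neutral from a coefficient's 95% credible interval."""
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if ci_high < 0:
        return "avoid"
    if ci_low > 0:
        return "select"
    return "neutral"


class HierarchicalRSF(BaseEstimator):
    """sklearn-style wrapper around :func:`fit_hierarchical_rsf`.

    ``fit`` takes the used/available DataFrame (response in the ``used``
    column, or passed separately as ``y``).  Fitted attributes: ``posterior_``,
    ``convergence_``, ``summary_``, ``year_summaries_``,
    ``individual_coefficients_``.
    """

    def __init__(self, priors: PriorSpec | None = None, n_chains: int = 3,
                 n_iterations: int = 3000, burn_in: int = 1200, thin: int = 3,
                 random_state: int = 0):
        self.priors = priors
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        table = X.copy()
        if y is not None:
            table["used"] = np.asarray(y)
        mcmc = MCMCConfig(n_chains=self.n_chains, n_iterations=self.n_iterations,
                          burn_in=self.burn_in, thin=self.thin,
                          seed=self.random_state)
        self.posterior_ = fit_hierarchical_rsf(table, priors=self.priors, mcmc=mcmc)
        self.convergence_ = check_convergence(self.posterior_)
        self.summary_ = self.posterior_.summary()
        self.year_summaries_ = derive_population_summaries(self.posterior_)
        self.individual_coefficients_ = self.posterior_.individual_coefficients()
        return self

    def selection_class(self, coef: str = "footprint") -> dict[int, str]:
        """Population-level avoid/select/neutral call per year."""
        out = {}
        for yr, s in self.year_summaries_.items():
            if isinstance(yr, int):
                out[yr] = classify_selection(s["mean"], s["ci_low"], s["ci_high"])
        return out
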