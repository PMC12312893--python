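"""Hierarchical RSF: likelihood, convergence diagnostic, derived summaries,
classification rule and sampler behaviour on small synthetic tables."""

import math

import numpy as np
import pandas as pd
import pytest

from footsel.rsf import (
    MCMCConfig,
    PriorSpec,
    RSFPosterior,
    check_convergence,
    classify_selection,
    derive_population_summaries,
    fit_hierarchical_rsf,
    gelman_rubin,
    published_mcmc_config,
    rsf_log_likelihood,
)
from footsel.terms import COEF_NAMES

from conftest import make_synthetic_ua_table


def _design(rows, indicators=None):
    """(X, y) from a list of covariate dicts + used flags, hand-assembled."""
    X = np.array([[1.0] + [r[c] for c in COEF_NAMES[1:]] for r, _ in rows])
    y = np.array([u for _, u in rows], dtype=float)
    if indicators is not None:
        for i, ind in enumerate(indicators):
            X[:, 4 + i] *= ind
    return X, y


class TestLogLikelihood:
    def test_all_zero_coefficients_give_n_log_half(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((37, 9))
        y = rng.integers(0, 2, 37).astype(float)
        assert rsf_log_likelihood(np.zeros(9), X, y) == pytest.approx(37 * math.log(0.5))

    def test_matches_term_by_term_hand_evaluation(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 9))
        y = rng.integers(0, 2, 10).astype(float)
        beta = rng.normal(0, 0.8, 9)
        expected = 0.0
        for i in range(10):
            eta = float(X[i] @ beta)
            p = 1.0 / (1.0 + math.exp(-eta))
            expected += y[i] * math.log(p) + (1 - y[i]) * math.log(1 - p)
        assert rsf_log_likelihood(beta, X, y) == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_masked_landcover_coefficient(self):
        rng = np.random.default_rng(2)
        rows = [({c: rng.normal() for c in COEF_NAMES[1:]}, int(rng.integers(0, 2)))
                for _ in range(20)]
        # water (last class) masked out
        X, y = _design(rows, indicators=[1, 1, 1, 1, 0])
        beta = rng.normal(size=9)
        beta2 = beta.copy()
        beta2[8] += 100.0  # water coefficient
        assert rsf_log_likelihood(beta, X, y) == rsf_log_likelihood(beta2, X, y)

    def test_stable_at_extreme_linear_predictors(self):
        X = np.full((2, 9), 77.0)
        y = np.array([1.0, 0.0])
        ll = rsf_log_likelihood(np.ones(9), X, y)
        assert np.isfinite(ll)

    def test_non_finite_covariate_rejected(self):
        X = np.zeros((3, 9))
        X[1, 2] = np.nan
        with pytest.raises(ValueError):
            rsf_log_likelihood(np.zeros(9), X, np.zeros(3))


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((3, 2000))
        assert float(gelman_rubin(chains)) == pytest.approx(1.0, abs=0.02)

    def test_offset_chain_flags_divergence(self):
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((3, 500))
        chains[0] += 10.0
        assert float(gelman_rubin(chains)) > 1.5

    def test_matches_direct_formula_on_toy(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((2, 100))
        # direct split-chain computation, written out independently
        halves = np.array([chains[0, :50], chains[0, 50:],
                           chains[1, :50], chains[1, 50:]])
        n = 50
        means = halves.mean(axis=1)
        W = halves.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert float(gelman_rubin(chains)) == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((3, 400)) + 0.2 * np.arange(400) / 400
        ours = float(gelman_rubin(chains))
        theirs = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"])
        assert ours == pytest.approx(theirs, abs=5e-3)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100)))


class TestClassification:
    @pytest.mark.parametrize("mean,lo,hi,expected", [
        (-1.88, -2.26, -1.50, "avoid"),    # published 2019 population mean
        (0.483, -0.003, 0.971, "neutral"),  # published mean individual change
        (0.5, 0.2, 0.9, "select"),
    ])
    def test_rule(self, mean, lo, hi, expected):
        assert classify_selection(mean, lo, hi) == expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_selection(0.0, 1.0, -1.0)


def _toy_posterior(draws_by_name, groups):
    names = list(draws_by_name)
    arr = np.stack([np.asarray(draws_by_name[n]) for n in names], axis=-1)
    return RSFPosterior(
        draws=arr, param_names=names, groups=pd.DataFrame(groups),
        indicators=pd.DataFrame(), mcmc=MCMCConfig(), priors=PriorSpec(),
    )


class TestPopulationSummaries:
    def _groups(self):
        return [
            {"individual_year_id": "A1_2019", "animal_id": "A1", "year": 2019,
             "population": "P1"},
            {"individual_year_id": "A1_2020", "animal_id": "A1", "year": 2020,
             "population": "P1"},
        ]

    def test_identical_years_difference_centred_at_zero(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal((2, 500))
        post = _toy_posterior({"beta[A1_2019].footprint": d,
                               "beta[A1_2020].footprint": d}, self._groups())
        s = derive_population_summaries(post)
        assert s["difference"]["mean"] == 0.0
        assert s["difference"]["ci_low"] == 0.0 == s["difference"]["ci_high"]

    def test_difference_mean_is_linear(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((2, 400))
        b = rng.standard_normal((2, 400)) + 0.7
        post = _toy_posterior({"beta[A1_2019].footprint": a,
                               "beta[A1_2020].footprint": b}, self._groups())
        s = derive_population_summaries(post)
        assert s["difference"]["mean"] == pytest.approx(b.mean() - a.mean(), abs=1e-12)

    def test_percentile_interval_matches_sorted_draws(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((2, 500))
        post = _toy_posterior({"beta[A1_2019].footprint": a,
                               "beta[A1_2020].footprint": a + 1}, self._groups())
        s = derive_population_summaries(post)
        lo, hi = np.percentile(np.sort(a.ravel()), [2.5, 97.5])
        assert s[2019]["ci_low"] == pytest.approx(lo)
        assert s[2019]["ci_high"] == pytest.approx(hi)


class TestPooledSummaries:
    def test_individual_vs_population_aggregation_differ_by_weighting(self):
        from footsel.rsf import pool_year_summaries
        rng = np.random.default_rng(11)
        # population A: 3 individuals near -2; population B: 1 individual near 0
        post_a = _toy_posterior(
            {f"beta[A{i}_2019].footprint": rng.normal(-2.0, 0.01, (2, 200))
             for i in range(3)},
            [{"individual_year_id": f"A{i}_2019", "animal_id": f"A{i}",
              "year": 2019, "population": "PA"} for i in range(3)])
        post_b = _toy_posterior(
            {"beta[B0_2019].footprint": rng.normal(0.0, 0.01, (2, 200))},
            [{"individual_year_id": "B0_2019", "animal_id": "B0",
              "year": 2019, "population": "PB"}])
        by_ind = pool_year_summaries([post_a, post_b], how="individuals")
        by_pop = pool_year_summaries([post_a, post_b], how="populations")
        assert by_ind[2019]["mean"] == pytest.approx(-1.5, abs=0.05)
        assert by_pop[2019]["mean"] == pytest.approx(-1.0, abs=0.05)


class TestMCMCConfig:
    def test_draw_bookkeeping_is_exact(self):
        cfg = MCMCConfig(n_chains=3, n_iterations=3000, burn_in=1200, thin=3)
        assert cfg.n_draws == 600
        full = published_mcmc_config()
        assert (full.n_chains, full.n_iterations, full.burn_in, full.thin) == \
            (3, 30000, 3000, 3)
        assert full.n_draws == 9000

    @pytest.mark.parametrize("kw", [
        {"burn_in": 3000, "n_iterations": 3000},
        {"thin": 0},
        {"n_iterations": 3001, "burn_in": 1200, "thin": 3},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            MCMCConfig(**kw)


class TestHierarchicalFit:
    @pytest.fixture(scope="class")
    def small_fit(self):
        rng = np.random.default_rng(10)
        truth = np.column_stack([
            rng.normal(-0.5, 0.5, 6),            # intercept
            rng.normal(-1.5, 0.4, 6),            # footprint
            rng.normal(0.5, 0.2, (6, 7))[:, :7],
        ])
        table = make_synthetic_ua_table(truth, n_used=80, ratio=10, seed=11)
        mcmc = MCMCConfig(n_chains=3, n_iterations=900, burn_in=300, thin=3, seed=1)
        return truth, fit_hierarchical_rsf(table, mcmc=mcmc)

    def test_draw_counts_match_config(self, small_fit):
        _, post = small_fit
        assert post.draws.shape[:2] == (3, 200)

    def test_posterior_means_track_truth(self, small_fit):
        truth, post = small_fit
        mu_fp = post.flat("mu.footprint")
        assert abs(mu_fp.mean() - truth[:, 1].mean()) < 0.6

    def test_convergence_report_has_all_parameters(self, small_fit):
        _, post = small_fit
        report = check_convergence(post)
        assert set(report.rhat) == set(post.param_names)

    def test_shrinkage_toward_pooled_estimate(self):
        # identical individuals (tau truth -> infinity): posterior spread of
        # individual coefficients is far smaller than the MLE spread
        beta = np.r_[-0.4, -1.5, 0.4, -0.2, np.zeros(5)]
        truth = np.tile(beta, (6, 1))
        table = make_synthetic_ua_table(truth, n_used=40, ratio=10, seed=12)
        mcmc = MCMCConfig(n_chains=2, n_iterations=600, burn_in=300, thin=3, seed=2)
        post = fit_hierarchical_rsf(table, mcmc=mcmc)
        coefs = post.individual_coefficients("footprint")["mean"]
        from footsel.rsf import _design_for_group, _laplace_proposal
        mles = []
        for key, grp in table.groupby("individual_year_id"):
            X, y, m = _design_for_group(grp)
            mles.append(_laplace_proposal(X, y, m)[0][1])
        assert coefs.std() < 0.8 * np.std(mles)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            fit_hierarchical_rsf(pd.DataFrame({"used": [0, 1]}))
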