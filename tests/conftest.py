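"""Shared fixtures: a small synthetic landscape and a fast generative
used/available table builder that bypasses the landscape machinery."""

import numpy as np
import pandas as pd
import pytest

from footsel.synthetic import (
    LandscapeConfig,
    build_covariate_stack,
    generate_landscape,
)
from footsel.terms import COEF_NAMES, COVARIATE_NAMES, LANDCOVER_CLASSES


@pytest.fixture(scope="session")
def small_landscape():
    config = LandscapeConfig(width_m=3000.0, height_m=3000.0)
    return generate_landscape(config, seed=7)


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    return build_covariate_stack(small_landscape)


def make_synthetic_ua_table(
    betas: np.ndarray,
    n_used: int = 150,
    ratio: int = 20,
    seed: int = 0,
    population: str = "P1",
    year: int = 2019,
    indicators: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact generative used/available table without a landscape.

    For each individual j with coefficient vector ``betas[j]`` (order of
    COEF_NAMES; the intercept is ignored by the conditional design), a pool
    of available covariate rows is drawn (footprint uniform on [0, 1],
    others standard normal), and used rows are categorical draws from that
    pool with probability proportional to exp(x' beta): the exact inverse
    of the used/available logistic estimand.
    """
    rng = np.random.default_rng(seed)
    betas = np.atleast_2d(betas)
    n_ind = betas.shape[0]
    if indicators is None:
        indicators = np.ones((n_ind, len(LANDCOVER_CLASSES)), dtype=int)
    parts = []
    for j in range(n_ind):
        n_av = n_used * ratio
        pool = np.column_stack([
            rng.uniform(0.0, 1.0, 4 * n_av),             # footprint
            rng.standard_normal((4 * n_av, len(COVARIATE_NAMES) - 1)),
        ])
        eff = betas[j, 1:].copy()
        for c in range(len(LANDCOVER_CLASSES)):
            if indicators[j, c] == 0:
                eff[3 + c] = 0.0
        w = np.exp(pool @ eff - (pool @ eff).max())
        used_idx = rng.choice(len(pool), size=n_used, p=w / w.sum())
        avail_idx = rng.choice(len(pool), size=n_av)
        rows = np.vstack([pool[used_idx], pool[avail_idx]])
        df = pd.DataFrame(rows, columns=list(COVARIATE_NAMES))
        df.insert(0, "used", np.r_[np.ones(n_used, int), np.zeros(n_av, int)])
        for c, cls in enumerate(LANDCOVER_CLASSES):
            df[f"ind_{cls}"] = indicators[j, c]
        df["individual_year_id"] = f"S{j + 1:02d}_{year}"
        df["animal_id"] = f"S{j + 1:02d}"
        df["year"] = year
        df["population"] = population
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


@pytest.fixture(scope="session")
def coef_order():
    return COEF_NAMES
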