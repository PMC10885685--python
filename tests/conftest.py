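"""Shared fixtures.

The two MCMC fixtures are session-scoped because they are the expensive
parts of the suite: a parameter-recovery fit on fully observed synthetic
cells, and a survey-realistic ("sparsity") end-to-end run used for the
precision comparisons.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from smalltrend.direct import direct_estimates
from smalltrend.domains import cell_table
from smalltrend.model import McmcConfig, SmallAreaTrendModel
from smalltrend.synthetic import TruthParams, draw_truth, simulate_survey

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

RECOVERY_TRUTH_SEED = 3
RECOVERY_COUNT_SEED = 7
RECOVERY_N_EFF = 500.0
SPARSITY_SEED = 2021


@pytest.fixture(scope="session")
def recovery_run():
    """Data simulated from the model itself (all 2352 cells, n_eff=500) and
    the reduced-MCMC refit used for parameter-recovery checks."""
    truth = draw_truth(TruthParams(), seed=RECOVERY_TRUTH_SEED)
    cells = cell_table()
    rng = np.random.default_rng(RECOVERY_COUNT_SEED)
    mu = truth.mu[cells["d"].to_numpy(), cells["year"].to_numpy() - 2001]
    data = cells[["state", "age_group", "sex", "year"]].copy()
    data["y_eff"] = rng.binomial(int(RECOVERY_N_EFF), mu).astype(float)
    data["n_eff"] = RECOVERY_N_EFF
    model = SmallAreaTrendModel(data)
    res = model.fit(McmcConfig(chains=2, burn_in=500, iterations=2000, thin=2, seed=5))
    return {"truth": truth, "data": data, "model": model, "results": res, "mu_true": mu}


@pytest.fixture(scope="session")
def sparsity_run():
    """Survey-realistic synthetic run: generator -> direct -> model fit."""
    sim = simulate_survey(seed=SPARSITY_SEED)
    est = direct_estimates(sim["waves"])
    model = SmallAreaTrendModel(est)
    res = model.fit(McmcConfig(chains=2, burn_in=300, iterations=1000, thin=2, seed=5))
    return {"sim": sim, "direct": est, "model": model, "results": res}


@pytest.fixture(scope="session")
def conjugate_toy():
    """20-observation conjugate normal toy with analytic posterior.

    Model: y_i ~ N(theta, sigma^2) with sigma known, theta ~ N(m0, s0^2).
    Returns observations, posterior moments, and a large draws x obs
    log-likelihood matrix.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(42)
    sigma, m0, s0 = 1.3, 0.0, 2.0
    y = rng.normal(0.7, sigma, size=20)
    n = len(y)
    post_prec = n / sigma**2 + 1 / s0**2
    post_var = 1.0 / post_prec
    post_mean = post_var * (y.sum() / sigma**2 + m0 / s0**2)
    theta = rng.normal(post_mean, np.sqrt(post_var), size=8000)
    ll = norm.logpdf(y[None, :], loc=theta[:, None], scale=sigma)
    return {
        "y": y,
        "sigma": sigma,
        "m0": m0,
        "s0": s0,
        "post_mean": post_mean,
        "post_var": post_var,
        "theta": theta,
        "loglik": ll,
    }
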