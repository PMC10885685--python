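"""Model assessment: predictive criteria, posterior predictive checks, and
the precision comparison between model-based and direct estimators.

The criteria follow the standard draw-based definitions. With ``ll`` the
(draws x observations) log-likelihood matrix:

* WAIC: ``lppd = sum_i log mean_s exp(ll_si)``, ``p_waic = sum_i
  Var_s(ll_si)``, ``waic = -2 (lppd - p_waic)``.
* DIC: ``p_dic = 2 (ll(theta_bar) - mean_s ll_s)``, ``dic = -2
  ll(theta_bar) + 2 p_dic``.
* LOOIC: Pareto-smoothed importance-sampling leave-one-out ELPD;
  ``looic = -2 elpd``. Observations with Pareto shape k > 0.7 are flagged
  as unreliable, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

PARETO_K_THRESHOLD = 0.7


def _check_ll(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood matrix must be draws x observations")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    return ll


def waic(loglik: np.ndarray) -> tuple[float, float]:
    """Return (waic, p_waic) from a draws x observations matrix."""
    ll = _check_ll(loglik)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def dic(loglik: np.ndarray, loglik_at_posterior_mean: np.ndarray) -> tuple[float, float]:
    """Return (dic, p_dic).

    ``loglik_at_posterior_mean`` is the per-observation log-likelihood
    evaluated at the posterior-mean parameters.
    """
    ll = _check_ll(loglik)
    ll_hat = float(np.sum(np.asarray(loglik_at_posterior_mean, dtype=float)))
    mean_ll = float(ll.sum(axis=1).mean())
    p_dic = 2.0 * (ll_hat - mean_ll)
    return -2.0 * ll_hat + 2.0 * p_dic, p_dic


@dataclass
class LooResult:
    elpd: float
    looic: float
    p_loo: float
    pareto_k: np.ndarray
    flagged: np.ndarray  # boolean per observation, k > 0.7


def loo_elpd(loglik: np.ndarray) -> LooResult:
    """PSIS leave-one-out expected log predictive density.

    Importance ratios for observation i are ``1 / p(y_i | theta_s)``; their
    tails are smoothed by a generalized-Pareto fit (via arviz's ``psislw``).
    """
    ll = _check_ll(loglik)
    if ll.shape[1] < 2:
        raise ValueError("LOO needs at least two observations (refit on an empty set is undefined)")
    from arviz.stats import psislw

    lw, k = psislw(-ll.T)  # arviz expects observations first
    lw = np.asarray(lw)
    k = np.asarray(k)
    elpd_i = logsumexp(ll.T + lw, axis=1)
    lppd_i = logsumexp(ll, axis=0) - np.log(ll.shape[0])
    elpd = float(elpd_i.sum())
    flagged = k > PARETO_K_THRESHOLD
    if flagged.any():
        logger.warning("PSIS-LOO: %d observation(s) with Pareto k > %.1f", flagged.sum(), PARETO_K_THRESHOLD)
    return LooResult(
        elpd=elpd,
        looic=-2.0 * elpd,
        p_loo=float(lppd_i.sum() - elpd),
        pareto_k=k,
        flagged=flagged,
    )


def fit_criteria(loglik: np.ndarray, loglik_at_posterior_mean: np.ndarray) -> dict:
    """All criteria in one JSON-ready dict (contributions sum to totals)."""
    w, p_w = waic(loglik)
    d, p_d = dic(loglik, loglik_at_posterior_mean)
    loo = loo_elpd(loglik)
    return {
        "waic": w,
        "p_waic": p_w,
        "dic": d,
        "p_dic": p_d,
        "elpd_loo": loo.elpd,
        "looic": loo.looic,
        "p_loo": loo.p_loo,
        "n_flagged_pareto_k": int(loo.flagged.sum()),
    }


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------


def _stat_year_mean(y, n, years):
    out = {}
    for yr in np.unique(years):
        m = years == yr
        out[int(yr)] = float(np.sum(y[m]) / np.sum(n[m]))
    return np.array([out[k] for k in sorted(out)])


_STATISTICS = {
    "year_mean": _stat_year_mean,
    "domain_max": lambda y, n, years: np.array([float(np.max(y / n))]),
    "zero_cells": lambda y, n, years: np.array([float(np.sum(y == 0))]),
}


def posterior_predictive_check(
    results,
    statistic: str = "year_mean",
    n_replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Tail probability Pr(T(y_rep) >= T(y_obs)) per statistic component.

    Replicate datasets are drawn binomially from the posterior prevalence
    draws at each observed cell's (rounded) effective size. Tail
    probabilities near 0 or 1 indicate systematic discrepancy between the
    observed data and the model's replicated data.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; one of {sorted(_STATISTICS)}")
    fn = _STATISTICS[statistic]
    model = results.model
    rng = np.random.default_rng(seed)
    y_obs, n_eff = model._y, model._n
    years = model.data["year"].to_numpy()
    n_int = np.maximum(np.rint(n_eff).astype(int), 1)

    # posterior mu at the observed cells, one draw per replicate
    obs_cols = _observed_cell_columns(model)
    t_obs = fn(y_obs, n_eff, years)
    draws_idx = rng.integers(0, results.n_draws, size=n_replicates)
    ge = np.zeros_like(t_obs, dtype=float)
    for ridx in draws_idx:
        mu = results.mu_draws[ridx, obs_cols].astype(float)
        y_rep = rng.binomial(n_int, mu).astype(float)
        t_rep = fn(y_rep, n_int.astype(float), years)
        ge += (t_rep >= t_obs).astype(float)
    p = ge / n_replicates
    labels = sorted(np.unique(years).tolist()) if statistic == "year_mean" else [statistic]
    return pd.DataFrame({"statistic": statistic, "component": labels, "p_tail": p})


def _observed_cell_columns(model) -> np.ndarray:
    from smalltrend.domains import N_YEARS, YEARS

    return model._d * N_YEARS + (model.data["year"].to_numpy() - YEARS[0])


# ---------------------------------------------------------------------------
# CV comparison (the precision-gain assessment)
# ---------------------------------------------------------------------------


def compare_cv(model_trend: pd.DataFrame, direct: pd.DataFrame) -> dict:
    """Compare model-based and direct CVs on common observed cells.

    ``model_trend`` is the detailed prediction table (state, age_group,
    sex, year, est, se); ``direct`` the direct-estimate table. Cells with a
    zero or missing direct estimate have an undefined CV and are excluded
    (logged). Returns per-cell table plus per-year summary (mean and max CV
    of each estimator and the share of direct cells above the 25% cut-off).
    """
    from smalltrend.direct import CV_CUTOFF_PCT

    merged = direct.merge(
        model_trend,
        on=["state", "age_group", "sex", "year"],
        how="inner",
        suffixes=("_direct", "_model"),
    )
    usable = (merged["yhat"] > 0) & (merged["est"] > 0)
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("compare_cv: excluded %d cell(s) with undefined CV", n_drop)
    merged = merged[usable].copy()
    merged["cv_direct"] = 100.0 * merged["se_direct"] / merged["yhat"]
    merged["cv_model"] = 100.0 * merged["se_model"] / merged["est"]

    per_year = (
        merged.groupby("year")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_cv_direct": g["cv_direct"].mean(),
                    "mean_cv_model": g["cv_model"].mean(),
                    "max_cv_direct": g["cv_direct"].max(),
                    "max_cv_model": g["cv_model"].max(),
                    "share_direct_above_cutoff": (g["cv_direct"] > CV_CUTOFF_PCT).mean(),
                    "share_model_above_cutoff": (g["cv_model"] > CV_CUTOFF_PCT).mean(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return {"cells": merged, "per_year": per_year}
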