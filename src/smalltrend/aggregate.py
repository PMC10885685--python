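"""Population-weighted aggregation of posterior prevalence draws.

Aggregation happens *before* summarization: for each posterior draw the
aggregate prevalence of a level cell (e.g. NSW in 2007, or males
nationally) is the population-weighted mean of its detailed-domain draws,
``sum_d pop_dt mu_dt / sum_d pop_dt``; the posterior mean, SD and
equal-tailed 95% interval are then taken across the aggregated draws. The
population weights are year-specific (estimated-resident-population
analogue).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from smalltrend.domains import N_YEARS, YEARS

logger = logging.getLogger(__name__)

#: level name -> grouping columns; national has no grouping column.
LEVELS: dict[str, list[str]] = {
    "national": [],
    "state": ["state"],
    "age": ["age_group"],
    "sex": ["sex"],
    "sex_age": ["sex", "age_group"],
    "sex_state": ["sex", "state"],
    "detailed": ["state", "age_group", "sex"],
}


def _level_cols(level: str) -> list[str]:
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; one of {sorted(LEVELS)}")
    return LEVELS[level]


def _cell_population(cells: pd.DataFrame, population: pd.DataFrame) -> np.ndarray:
    merged = cells.merge(population, on=["state", "age_group", "sex", "year"], how="left")
    pop = merged["pop"].to_numpy(dtype=float)
    if np.any(~np.isfinite(pop)):
        raise ValueError("population table does not cover all domain-year cells")
    return pop


def aggregate_draws(
    mu_draws: np.ndarray,
    cells: pd.DataFrame,
    population: pd.DataFrame,
    level: str = "national",
) -> pd.DataFrame:
    """Aggregate detailed prevalence draws to a higher level.

    Parameters
    ----------
    mu_draws
        (n_draws, n_cells) prevalence draws aligned with ``cells`` rows.
    cells
        Domain-year cells (state, age_group, sex, year), one per column of
        ``mu_draws``.
    population
        Complete domain-year population table (state, age_group, sex, year,
        pop).
    level
        One of ``national, state, age, sex, sex_age, sex_state, detailed``.

    Returns
    -------
    One row per level-cell and year with ``level, cell, year, est, se,
    lo95, hi95``.
    """
    cols = _level_cols(level)
    pop = _cell_population(cells, population)
    mu = np.asarray(mu_draws, dtype=float)
    if mu.shape[1] != len(cells):
        raise ValueError("mu_draws and cells are misaligned")

    group_keys = cells[cols + ["year"]] if cols else cells[["year"]]
    rows = []
    for key, idx in group_keys.groupby(cols + ["year"] if cols else "year", sort=True).indices.items():
        if cols:
            key = key if isinstance(key, tuple) else (key,)
            year = key[-1]
            label = "/".join(str(k) for k in key[:-1]) if cols else "all"
        else:
            year, label = key, "all"
        w = pop[idx]
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"zero population for level cell {label!r} in {year}")
        agg = mu[:, idx] @ (w / tot)
        lo, hi = np.percentile(agg, [2.5, 97.5])
        rows.append(
            {
                "level": level,
                "cell": label,
                "year": int(year),
                "est": float(agg.mean()),
                "se": float(agg.std(ddof=1)) if len(agg) > 1 else 0.0,
                "lo95": float(lo),
                "hi95": float(hi),
            }
        )
    return pd.DataFrame(rows).sort_values(["cell", "year"], ignore_index=True)


def aggregate_direct(
    direct: pd.DataFrame, population: pd.DataFrame, level: str = "national"
) -> pd.DataFrame:
    """Aggregate direct estimates with the same population weights.

    Weighted mean of the domain estimates over the level's observed domains;
    the SE combines the domain jackknife SEs as
    ``sqrt(sum (w_d/W)^2 se_d^2)`` (independence across domains).
    """
    cols = _level_cols(level)
    merged = direct.merge(population, on=["state", "age_group", "sex", "year"], how="left")
    rows = []
    for key, grp in merged.groupby(cols + ["year"] if cols else "year", sort=True):
        if cols:
            key = key if isinstance(key, tuple) else (key,)
            year, label = key[-1], "/".join(str(k) for k in key[:-1])
        else:
            year, label = key, "all"
        w = grp["pop"].to_numpy(float)
        tot = w.sum()
        if tot <= 0:
            continue
        est = float(np.dot(w, grp["yhat"]) / tot)
        se = float(np.sqrt(np.sum((w / tot) ** 2 * grp["se"].to_numpy() ** 2)))
        rows.append({"level": level, "cell": label, "year": int(year), "est": est, "se": se})
    return pd.DataFrame(rows).sort_values(["cell", "year"], ignore_index=True)


def benchmark(trends: pd.DataFrame, direct_aggregated: pd.DataFrame) -> pd.DataFrame:
    """Consistency check of aggregated model trends against direct estimates.

    Per level-cell and survey year: difference (model - direct),
    standardized difference (difference / direct SE) and a flag when the
    standardized difference exceeds 2 in magnitude. Years without a direct
    value are skipped (logged).
    """
    merged = trends.merge(
        direct_aggregated, on=["level", "cell", "year"], suffixes=("_model", "_direct"), how="left"
    )
    missing = merged["est_direct"].isna()
    for _, r in merged[missing].iterrows():
        logger.info("no direct estimate for %s %s %d; skipped", r["level"], r["cell"], r["year"])
    merged = merged[~missing].copy()
    merged["diff"] = merged["est_model"] - merged["est_direct"]
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["std_diff"] = merged["diff"] / merged["se_direct"]
    merged["flag"] = merged["std_diff"].abs() > 2
    return merged[
        ["level", "cell", "year", "est_model", "est_direct", "se_direct", "diff", "std_diff", "flag"]
    ].reset_index(drop=True)
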