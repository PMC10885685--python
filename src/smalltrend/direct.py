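"""Survey-weighted direct estimation.

For each detailed domain-year the direct estimator is the weighted mean of
the binary outcome with weights normalized within the domain-year,
``yhat = sum_j w_j y_j / sum_j w_j``. Its standard error uses the
delete-a-group jackknife over the R replicate-weight columns,

    SE = sqrt( (R-1)/R * sum_c (yhat^(c) - yhat)^2 ),

the standard delete-a-group factor. The coefficient of variation is
``100 * SE / yhat`` with a 25% use-with-caution cut-off, and the model's
data input is the effective-sample-size binomial pair
``n_eff = yhat (1 - yhat) / SE^2``, ``y_eff = n_eff * yhat`` (the design
effect identity), kept real-valued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CV_CUTOFF_PCT = 25.0  # relative-standard-error threshold for "use with caution"


def _replicate_cols(sample: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in sample.columns if c.startswith("rw_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return cols


def direct_prevalence(sample: pd.DataFrame, weight_col: str = "weight") -> float:
    """Weighted prevalence of ``smoker`` over the given person rows.

    Weights are normalized internally to sum to 1; returns ``nan`` for an
    empty table (a domain-year with no respondents is missing, not zero).
    """
    if len(sample) == 0:
        return float("nan")
    w = sample[weight_col].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights are not allowed")
    tot = w.sum()
    if tot == 0:
        return float("nan")
    return float(np.dot(w, sample["smoker"].to_numpy(dtype=float)) / tot)


def jackknife_se(sample: pd.DataFrame) -> float:
    """Delete-a-group jackknife SE of the weighted prevalence.

    Surveys with different replicate counts can be stacked: replicate
    columns that are entirely missing for this subset (e.g. rw_31..rw_60
    for a 30-replicate wave) are ignored, so R is the wave's own count.
    """
    cols = [c for c in _replicate_cols(sample) if not sample[c].isna().all()]
    if not cols:
        raise ValueError("sample has no replicate-weight columns (rw_1..rw_R)")
    R = len(cols)
    yhat = direct_prevalence(sample)
    if np.isnan(yhat):
        return float("nan")
    reps = np.array([direct_prevalence(sample, weight_col=c) for c in cols])
    # replicate with no retained weight in this cell: treat as the full estimate
    reps = np.where(np.isnan(reps), yhat, reps)
    return float(np.sqrt((R - 1.0) / R * np.sum((reps - yhat) ** 2)))


def coefficient_of_variation(yhat: float, se: float) -> tuple[float, bool]:
    """CV in percent and the above-25% caution flag.

    Returns ``(nan, False)`` when the estimate is 0 (or missing), where the
    CV is undefined.
    """
    if not np.isfinite(yhat) or yhat == 0:
        return float("nan"), False
    cv = 100.0 * se / yhat
    return float(cv), bool(cv > CV_CUTOFF_PCT)


@dataclass
class EffectiveCounts:
    n_eff: float
    y_eff: float
    boundary_adjusted: bool
    capped: bool = False


#: n_eff larger than this multiple of the respondent count (design effect
#: below 1/4) is treated as a variance-estimation artifact and capped.
MAX_NEFF_OVER_N = 4.0


def effective_counts(
    yhat: float, se: float, n: int, y_unweighted: float | None = None
) -> EffectiveCounts:
    """Effective binomial counts from the design-effect identity.

    ``n_eff = yhat (1-yhat) / se^2`` and ``y_eff = n_eff * yhat``. Boundary
    cells (yhat in {0,1} or se numerically 0) would carry infinite
    information, so the estimate is shrunk to ``yhat* = (y + 0.5)/(n + 1)``
    (y = observed smoker count) and the simple-random-sampling variance at
    ``yhat*`` is used, which reduces to ``n_eff = n``; such cells are
    flagged. A jackknife SE far below the SRS value (design effect < 1/4,
    possible in tiny cells with few replicate groups) is likewise treated
    as an artifact: n_eff is capped at ``4 n`` and the cell flagged.
    """
    if n <= 0 or not np.isfinite(yhat):
        raise ValueError("effective counts require an observed cell")
    if 0.0 < yhat < 1.0 and se > 1e-10:
        n_eff = yhat * (1.0 - yhat) / se**2
        if n_eff > MAX_NEFF_OVER_N * n:
            n_eff = MAX_NEFF_OVER_N * n
            return EffectiveCounts(float(n_eff), float(n_eff * yhat), False, True)
        return EffectiveCounts(float(n_eff), float(n_eff * yhat), False)
    y = yhat * n if y_unweighted is None else y_unweighted
    ystar = (y + 0.5) / (n + 1.0)
    return EffectiveCounts(float(n), float(n * ystar), True)


def direct_estimates(waves: dict[int, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Direct estimates for every observed domain-year.

    Parameters
    ----------
    waves
        Either a mapping year -> person-level table, or one concatenated
        table covering several years; tables follow the survey CSV schema
        (``state, age_group, sex, smoker, weight, rw_1..rw_R``).

    Returns
    -------
    One row per domain-year that has at least one respondent, with columns
    ``state, age_group, sex, year, n, yhat, se, cv_pct, n_eff, y_eff, flag``.
    ``flag`` is ``""``, ``"high_cv"``, ``"boundary"`` or ``"deff_lt_1"``
    (the latter marking n_eff > n, possible when the design effect < 1).
    Domain-years with no respondents are simply absent (missing, not zero).
    """
    if isinstance(waves, dict):
        table = pd.concat(waves.values(), ignore_index=True)
    else:
        table = waves
    rows = []
    for (state, age, sex, year), grp in table.groupby(
        ["state", "age_group", "sex", "year"], sort=True, observed=True
    ):
        n = len(grp)
        yhat = direct_prevalence(grp)
        se = jackknife_se(grp)
        cv, high = coefficient_of_variation(yhat, se)
        eff = effective_counts(yhat, se, n, y_unweighted=float(grp["smoker"].sum()))
        flags = []
        if eff.boundary_adjusted:
            flags.append("boundary")
        elif eff.capped:
            flags.append("n_eff_capped")
        elif eff.n_eff > n:
            flags.append("deff_lt_1")
        if high:
            flags.append("high_cv")
        rows.append(
            {
                "state": state,
                "age_group": age,
                "sex": sex,
                "year": year,
                "n": n,
                "yhat": yhat,
                "se": se,
                "cv_pct": cv,
                "n_eff": eff.n_eff,
                "y_eff": eff.y_eff,
                "flag": "+".join(flags),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["year", "state", "age_group", "sex"], ignore_index=True)


def write_direct_csv(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, index=False)
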