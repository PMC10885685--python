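"""Joinpoint (segmented log-linear) trend regression.

An annual prevalence series ``p_t > 0`` is modelled on the log scale as a
continuous piecewise-linear function of time with K joinpoints tau_1 < ...
< tau_K (years where the slope changes), via the hinge basis

    log p_t = a + b t + sum_k delta_k max(0, t - tau_k).

For fixed K the joinpoint locations are found by exhaustive grid search
(joinpoints on the observation grid, at least 2 years between joinpoints
and none in the first/last 2 years), minimizing the residual sum of
squares. K itself is chosen by the sequential permutation-test procedure:
test K = k_min against K = k_max on a residual-permutation null with a
Bonferroni-adjusted level, raising k_min on rejection and lowering k_max
otherwise, until they meet.

The slope of segment k is ``beta_k = b + sum_{j<=k} delta_j``; the annual
percent change is ``APC_k = 100 (exp(beta_k) - 1)`` and the average annual
percent change over a period is ``AAPC = 100 (exp(sum w_k beta_k / sum
w_k) - 1)`` with calendar-year weights, its CI by the delta method on the
weighted slope.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_GAP = 2  # observed years between joinpoints
MIN_TAIL = 2  # joinpoint-free years at each end of the series


def _candidate_placements(T: int, k: int) -> list[tuple[int, ...]]:
    """All admissible joinpoint index tuples for a series of length T."""
    if k == 0:
        return [()]
    cand = range(MIN_TAIL, T - MIN_TAIL)
    out = [
        c
        for c in itertools.combinations(cand, k)
        if all(c[i + 1] - c[i] >= MIN_GAP for i in range(k - 1))
    ]
    if not out:
        raise ValueError(f"series of length {T} admits no placement of {k} joinpoints")
    return out


def _basis(t: np.ndarray, taus: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for tau in taus:
        cols.append(np.maximum(0.0, t - tau))
    return np.column_stack(cols)


@dataclass
class JoinpointResults:
    """A fitted segmented trend for one series."""

    years: np.ndarray
    values: np.ndarray
    k: int
    joinpoint_years: tuple[int, ...]
    coef: np.ndarray  # (a, b, delta_1..delta_K)
    cov: np.ndarray
    rss: float
    df_resid: int
    selection_pvalues: list[float] = field(default_factory=list)

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        edges = [int(self.years[0]), *self.joinpoint_years, int(self.years[-1])]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def segment_slopes(self) -> pd.DataFrame:
        """Per-segment log-scale slope, SE and APC with 95% CI."""
        rows = []
        tq = stats.t.ppf(0.975, self.df_resid) if self.df_resid > 0 else np.nan
        for k, (start, end) in enumerate(self.segment_bounds):
            c = np.zeros(len(self.coef))
            c[1] = 1.0
            c[2 : 2 + k] = 1.0
            slope = float(c @ self.coef)
            se = float(np.sqrt(c @ self.cov @ c))
            lo, hi = slope - tq * se, slope + tq * se
            rows.append(
                {
                    "segment": k,
                    "start": start,
                    "end": end,
                    "slope": slope,
                    "slope_se": se,
                    "apc": apc(slope),
                    "apc_lo95": apc(lo),
                    "apc_hi95": apc(hi),
                }
            )
        return pd.DataFrame(rows)

    def aapc(self, period: tuple[int, int] | None = None) -> dict:
        """Average annual percent change over ``period`` (default: all).

        Weights are the calendar years each segment contributes to the
        period; CI and test statistic by the delta method on the weighted
        slope.
        """
        y0, y1 = period if period is not None else (int(self.years[0]), int(self.years[-1]))
        if y1 <= y0 or y1 < self.years[0] or y0 > self.years[-1]:
            raise ValueError(f"period {period!r} does not overlap the fitted range")
        weights = np.zeros(self.k + 1)
        for k, (start, end) in enumerate(self.segment_bounds):
            weights[k] = max(0.0, min(end, y1) - max(start, y0))
        if weights.sum() == 0:
            raise ValueError("empty overlap between period and fitted segments")
        w = weights / weights.sum()
        c = np.zeros(len(self.coef))
        c[1] = 1.0
        for k in range(1, self.k + 1):
            c[1 + k] = w[k:].sum()  # delta_k contributes to segments k..K
        wslope = float(c @ self.coef)
        se = float(np.sqrt(c @ self.cov @ c))
        tq = stats.t.ppf(0.975, self.df_resid) if self.df_resid > 0 else np.nan
        stat = wslope / se if se > 0 else np.inf * np.sign(wslope)
        p = 2 * stats.t.sf(abs(stat), self.df_resid) if self.df_resid > 0 else np.nan
        return {
            "aapc": apc(wslope),
            "lo95": apc(wslope - tq * se),
            "hi95": apc(wslope + tq * se),
            "stat": stat,
            "p": p,
            "weighted_slope": wslope,
            "weighted_slope_se": se,
        }

    def summary(self) -> str:
        seg = self.segment_slopes()
        a = self.aapc()
        lines = [
            f"Joinpoint fit: K={self.k} joinpoint(s) at {list(self.joinpoint_years)}",
            seg.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
            (
                f"AAPC {self.years[0]}-{self.years[-1]}: {a['aapc']:.2f}% "
                f"(95% CI {a['lo95']:.2f} to {a['hi95']:.2f}), stat={a['stat']:.2f}, p={a['p']:.3g}"
            ),
        ]
        return "\n".join(lines)


def apc(slope: float) -> float:
    """Annual percent change of a log-scale slope: 100 (exp(slope) - 1)."""
    return float(100.0 * np.expm1(slope))


class JoinpointModel:
    """Segmented log-linear trend model for one annual series.

    Parameters
    ----------
    years, values
        Strictly increasing annual years and strictly positive prevalences.
    se
        Optional per-year standard errors; when given with
        ``weighted=True``, generalized least squares with weights
        ``(value/se)^2`` (the log-scale inverse variances) is used instead
        of ordinary least squares.
    """

    def __init__(self, years, values, se=None, weighted: bool = False):
        self.years = np.asarray(years, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("values must be strictly positive (log is taken)")
        if len(self.years) != len(self.values) or len(self.years) < 3:
            raise ValueError("need matching years/values with at least 3 points")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive annual values")
        self._logy = np.log(self.values)
        if weighted:
            if se is None:
                raise ValueError("weighted fit requires per-year standard errors")
            w = (self.values / np.asarray(se, dtype=float)) ** 2
            self._sqrtw = np.sqrt(w / w.mean())
        else:
            self._sqrtw = np.ones_like(self.values)

    @property
    def T(self) -> int:
        return len(self.years)

    # -- fixed-K fit -----------------------------------------------------------

    def fit(self, k: int = 0) -> JoinpointResults:
        """Best fit with exactly k joinpoints (exhaustive grid search)."""
        placements = _candidate_placements(self.T, k)
        best = None
        yw = self._logy * self._sqrtw
        for pl in placements:
            Xw = _basis(self.years, tuple(self.years[list(pl)])) * self._sqrtw[:, None]
            coef, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            rss = float(res[0]) if res.size else float(np.sum((yw - Xw @ coef) ** 2))
            if best is None or rss < best[0]:
                best = (rss, pl, coef, Xw)
        rss, pl, coef, Xw = best
        df = self.T - (2 + k)
        sigma2 = rss / df if df > 0 else 0.0
        cov = sigma2 * np.linalg.pinv(Xw.T @ Xw)
        return JoinpointResults(
            years=self.years,
            values=self.values,
            k=k,
            joinpoint_years=tuple(int(self.years[i]) for i in pl),
            coef=coef,
            cov=cov,
            rss=rss,
            df_resid=df,
        )

    def _min_rss_batch(self, Y: np.ndarray, k: int) -> np.ndarray:
        """Min-over-placements RSS for each column of Y (T x B)."""
        placements = _candidate_placements(self.T, k)
        best = np.full(Y.shape[1], np.inf)
        for pl in placements:
            Xw = _basis(self.years, tuple(self.years[list(pl)])) * self._sqrtw[:, None]
            Q, _ = np.linalg.qr(Xw)
            resid = Y - Q @ (Q.T @ Y)
            rss = np.einsum("ij,ij->j", resid, resid)
            np.minimum(best, rss, out=best)
        return best

    # -- selection of K --------------------------------------------------------

    def permutation_test(
        self, k0: int, k1: int, n_perm: int = 499, seed: int = 0, rng=None
    ) -> float:
        """Permutation p-value of H0: K=k0 against Ha: K=k1 (k1 > k0).

        Residuals of the best K=k0 fit are permuted and added back to its
        fitted values; the test statistic is RSS(k0)/RSS(k1).
        """
        if k1 <= k0:
            raise ValueError("k1 must exceed k0")
        rng = np.random.default_rng(seed) if rng is None else rng
        fit0 = self.fit(k0)
        yw = self._logy * self._sqrtw
        rss0, rss1 = fit0.rss, float(self._min_rss_batch(yw[:, None], k1)[0])
        if rss1 <= 0:
            return 0.0 if rss0 > rss1 else 1.0
        stat_obs = rss0 / rss1
        Xw0 = _basis(self.years, tuple(float(j) for j in fit0.joinpoint_years)) * self._sqrtw[:, None]
        coef0, *_ = np.linalg.lstsq(Xw0, yw, rcond=None)
        fitted = Xw0 @ coef0
        resid = yw - fitted
        perm = np.array([rng.permutation(resid) for _ in range(n_perm)]).T  # T x n_perm
        Y = fitted[:, None] + perm
        r0 = self._min_rss_batch(Y, k0)
        r1 = self._min_rss_batch(Y, k1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat_perm = np.where(r1 > 0, r0 / r1, np.inf)
        return float((1 + np.sum(stat_perm >= stat_obs)) / (n_perm + 1))

    def select(
        self, k_max: int = 4, alpha: float = 0.05, n_perm: int = 499, seed: int = 0
    ) -> JoinpointResults:
        """Choose the number of joinpoints by sequential permutation tests.

        Bonferroni-adjusted level alpha/(k_max - k_min) at each stage,
        testing the current lower bound against the current upper bound;
        rejection raises the lower bound, otherwise the upper bound drops.
        A flat series degenerates to K=0.
        """
        max_k_feasible = 0
        while max_k_feasible < k_max:
            try:
                _candidate_placements(self.T, max_k_feasible + 1)
            except ValueError:
                break
            max_k_feasible += 1
        k_min, k_hi = 0, max_k_feasible
        rng = np.random.default_rng(seed)
        pvals = []
        while k_min < k_hi:
            level = alpha / (k_hi - k_min)
            p = self.permutation_test(k_min, k_hi, n_perm=n_perm, rng=rng)
            pvals.append(p)
            if p <= level:
                k_min += 1
            else:
                k_hi -= 1
        out = self.fit(k_min)
        out.selection_pvalues = pvals
        return out


def fit_segmented(years, values, k: int, se=None, weighted: bool = False) -> JoinpointResults:
    """Functional wrapper around :meth:`JoinpointModel.fit`."""
    return JoinpointModel(years, values, se=se, weighted=weighted).fit(k)


def select_joinpoints(
    years, values, k_max: int = 4, alpha: float = 0.05, n_perm: int = 499, seed: int = 0, se=None
) -> JoinpointResults:
    """Functional wrapper around :meth:`JoinpointModel.select`."""
    return JoinpointModel(years, values, se=se).select(
        k_max=k_max, alpha=alpha, n_perm=n_perm, seed=seed
    )


def batch_joinpoint(
    trends: pd.DataFrame,
    k_max: int = 4,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
) -> pd.DataFrame:
    """Joinpoint selection for every series in a trend table.

    ``trends`` stacks :func:`smalltrend.aggregate.aggregate_draws` outputs
    (columns level, cell, year, est, and optionally se). Series with any
    nonpositive value are skipped with a log entry. Returns one row per
    series mirroring the usual joinpoint report layout: series, level, K,
    joinpoint_years, segment_APCs, AAPC, LL, UL, stat, p.
    """
    rows = []
    for (level, cell), grp in trends.groupby(["level", "cell"], sort=True):
        grp = grp.sort_values("year")
        if (grp["est"] <= 0).any():
            logger.warning("series %s/%s has nonpositive values; skipped", level, cell)
            continue
        res = select_joinpoints(
            grp["year"].to_numpy(),
            grp["est"].to_numpy(),
            k_max=k_max,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        )
        a = res.aapc()
        seg = res.segment_slopes()
        rows.append(
            {
                "series": f"{level}:{cell}",
                "level": level,
                "cell": cell,
                "K": res.k,
                "joinpoint_years": ";".join(str(j) for j in res.joinpoint_years),
                "segment_APCs": ";".join(f"{x:.2f}" for x in seg["apc"]),
                "AAPC": a["aapc"],
                "LL": a["lo95"],
                "UL": a["hi95"],
                "stat": a["stat"],
                "p": a["p"],
            }
        )
    return pd.DataFrame(rows)
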