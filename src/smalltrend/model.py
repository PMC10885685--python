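"""Hierarchical Bayesian binomial-logit multilevel time-series model.

The model treats the effective smoker count of each observed domain-year
cell as (continuous) binomial,

    y_eff_dt ~ Binomial(n_eff_dt, mu_dt),
    logit(mu_dt) = beta' x_dt + v_d + z_t v_d^yr + u_t^(sex-age),

with 22 fixed effects (intercept, standardized year, sex, age, state and
sex-by-age contrasts; references female / 18-24 / ACT), independent domain
random intercepts ``v_d ~ N(0, sigma_I^2)`` and slopes ``v_d^yr ~ N(0,
sigma_S^2)``, and one first-order random-walk series per sex-by-age cell
sharing a scalar innovation variance ``sigma_RW1^2`` (sum-to-zero over time
for identifiability). Priors: N(0, 100) per fixed effect and half-normal
(scale 1 by default) on the three standard deviations. The binomial
dispersion is fixed at 1.

Fitting is by blocked Gibbs sampling with Polya-Gamma data augmentation:
conditional on the auxiliary variables all Gaussian blocks are conjugate and
drawn exactly; the three scales are updated by univariate slice sampling.
Non-survey years have no likelihood contribution, so their prevalence is
interpolated automatically through the linear year term and the random
walk. Convergence is monitored with split-chain R-hat (< 1.1 declares
convergence) and effective sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from smalltrend._polya_gamma import pg_draw
from smalltrend.design import build_design, design_columns
from smalltrend.domains import (
    N_DOMAINS,
    N_YEARS,
    SEX_AGE_CELLS,
    YEARS,
    cell_table,
    domain_index,
)

logger = logging.getLogger(__name__)

_MU_CLAMP = 1e-12  # numerical clamping of mu away from {0,1}
N_SERIES = len(SEX_AGE_CELLS)


@dataclass
class ModelSpec:
    """Structure of the multilevel time-series model.

    The shipped default is the full model above. Components can be switched
    off (their variance is then fixed at zero), and ``rw_order=2`` swaps the
    temporal term for a second-order walk as a comparison variant.
    """

    domain_intercept: bool = True
    domain_slope: bool = True
    rw: bool = True
    rw_order: int = 1
    beta_prior_var: float = 100.0
    sigma_prior_scale: float = 1.0  # half-normal scale for the three SDs

    def validate(self) -> None:
        if self.rw_order not in (1, 2):
            raise ValueError("rw_order must be 1 or 2")
        if self.beta_prior_var <= 0 or self.sigma_prior_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    """MCMC protocol. Defaults retain 3 x 10000/5 = 6000 draws."""

    chains: int = 3
    burn_in: int = 1000
    iterations: int = 10000
    thin: int = 5
    seed: int = 0

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain

    def validate(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.thin < 1 or self.burn_in < 0:
            raise ValueError("invalid MCMC configuration")


def _slice_sample(x0, logp, rng, w=0.5, max_steps=50):
    """Univariate slice sampler with stepping-out, on an unbounded scale."""
    ly = logp(x0) + np.log(rng.uniform())
    lo, hi = x0 - w * rng.uniform(), 0.0
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) <= ly:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= ly:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > ly:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _rw_prior_precision(T: int, order: int) -> np.ndarray:
    """Unscaled structure matrix D'D of an order-1 or order-2 random walk."""
    D = np.diff(np.eye(T), n=order, axis=0)
    return D.T @ D


class SmallAreaTrendModel:
    """Small-area prevalence trend model over the 112 x 21 domain-year grid.

    Parameters
    ----------
    data
        Direct-estimate table with one row per *observed* domain-year:
        columns ``state, age_group, sex, year, y_eff, n_eff`` (the output
        of :func:`smalltrend.direct.direct_estimates`). Non-survey and
        zero-sample cells are simply absent.
    spec
        Optional :class:`ModelSpec`.

    Examples
    --------
    >>> model = SmallAreaTrendModel(direct_df)
    >>> res = model.fit(McmcConfig(chains=2, iterations=2000, thin=2))
    >>> res.summary()
    >>> trend = res.predict_prevalence()
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.spec.validate()
        req = {"state", "age_group", "sex", "year", "y_eff", "n_eff"}
        missing = req - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        data = data.reset_index(drop=True)
        if np.any(data["n_eff"].to_numpy() <= 0):
            raise ValueError("n_eff must be positive for every observed cell")
        y, n = data["y_eff"].to_numpy(float), data["n_eff"].to_numpy(float)
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("y_eff must lie in [0, n_eff]")
        self.data = data

        self.cells = cell_table()
        Xf = build_design(self.cells)
        self.param_names = design_columns()
        self._X_full = Xf.to_numpy()
        self._d_full = self.cells["d"].to_numpy()
        self._t_full = self.cells["year"].to_numpy() - YEARS[0]
        self._s_full = self.cells["sex_age"].to_numpy()
        self._z_full = self._X_full[:, 1]

        self._X = build_design(data).to_numpy()
        self._d = domain_index(data)
        self._t = data["year"].to_numpy() - YEARS[0]
        self._s = np.array(
            [SEX_AGE_CELLS.index((sx, ag)) for sx, ag in zip(data["sex"], data["age_group"])]
        )
        self._z = self._X[:, 1]
        self._y = y
        self._n = n
        self._kappa = y - n / 2.0
        self._st = self._s * N_YEARS + self._t  # composite index into u.ravel()
        dom = self.cells.drop_duplicates("d").sort_values("d")
        self._dom_series = dom["sex_age"].to_numpy()  # series of each domain
        self._n_dom_per_series = np.bincount(self._dom_series, minlength=N_SERIES).astype(float)
        # log binomial coefficient, continuous via log-gamma
        self._lchoose = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)

    # -- likelihood / posterior ------------------------------------------------

    def linear_predictor(self, beta, v=None, v_yr=None, u=None, full=False):
        """eta for observed cells (default) or all 2352 cells (full=True)."""
        X, d, z, s, t = (
            (self._X_full, self._d_full, self._z_full, self._s_full, self._t_full)
            if full
            else (self._X, self._d, self._z, self._s, self._t)
        )
        eta = X @ np.asarray(beta, float)
        if v is not None:
            eta = eta + np.asarray(v)[d]
        if v_yr is not None:
            eta = eta + z * np.asarray(v_yr)[d]
        if u is not None:
            eta = eta + np.asarray(u)[s, t]
        return eta

    def loglik(self, eta: np.ndarray) -> np.ndarray:
        """Per-observation continuous-binomial log-likelihood at eta."""
        mu = np.clip(expit(eta), _MU_CLAMP, 1.0 - _MU_CLAMP)
        return self._lchoose + self._y * np.log(mu) + (self._n - self._y) * np.log1p(-mu)

    def log_posterior(self, state: dict) -> float:
        """Log posterior density (up to no constant: all normalizers kept).

        ``state`` maps ``beta`` (22,), and optionally ``v`` (112,), ``v_yr``
        (112,), ``u`` (14, 21), ``sigma_I``, ``sigma_S``, ``sigma_RW`` to
        values. Components absent from the spec must be absent here.
        """
        sp = self.spec
        beta = np.asarray(state["beta"], float)
        v = state.get("v") if sp.domain_intercept else None
        v_yr = state.get("v_yr") if sp.domain_slope else None
        u = state.get("u") if sp.rw else None
        lp = float(self.loglik(self.linear_predictor(beta, v, v_yr, u)).sum())
        lp += float(
            -0.5 * np.sum(beta**2) / sp.beta_prior_var
            - 0.5 * len(beta) * np.log(2 * np.pi * sp.beta_prior_var)
        )

        def _normal(x, sd):
            return float(-0.5 * np.sum(x**2) / sd**2 - x.size * np.log(sd * np.sqrt(2 * np.pi)))

        def _half_normal(sd):
            s = sp.sigma_prior_scale
            return float(-0.5 * sd**2 / s**2 + np.log(2.0) - np.log(s * np.sqrt(2 * np.pi)))

        if v is not None:
            lp += _normal(np.asarray(v), state["sigma_I"]) + _half_normal(state["sigma_I"])
        if v_yr is not None:
            lp += _normal(np.asarray(v_yr), state["sigma_S"]) + _half_normal(state["sigma_S"])
        if u is not None:
            inc = np.diff(np.asarray(u), n=sp.rw_order, axis=1)
            lp += _normal(inc, state["sigma_RW"]) + _half_normal(state["sigma_RW"])
        return lp

    # -- sampler ---------------------------------------------------------------

    def fit(self, config: McmcConfig | None = None) -> "SmallAreaTrendResults":
        """Run the Gibbs sampler and return a results object."""
        config = config or McmcConfig()
        config.validate()
        sp = self.spec
        n_obs = len(self._y)
        kept = config.retained_per_chain
        n_cells = len(self.cells)

        beta_ch = np.empty((config.chains, kept, len(self.param_names)))
        v_ch = np.empty((config.chains, kept, N_DOMAINS)) if sp.domain_intercept else None
        vyr_ch = np.empty((config.chains, kept, N_DOMAINS)) if sp.domain_slope else None
        u_ch = np.empty((config.chains, kept, N_SERIES, N_YEARS)) if sp.rw else None
        sig_ch = np.empty((config.chains, kept, 3))
        mu_ch = np.empty((config.chains, kept, n_cells), dtype=np.float32)
        ll_ch = np.empty((config.chains, kept, n_obs))

        for chain in range(config.chains):
            rng = np.random.default_rng([config.seed, chain])
            self._run_chain(
                rng,
                config,
                chain,
                beta_ch,
                v_ch,
                vyr_ch,
                u_ch,
                sig_ch,
                mu_ch,
                ll_ch,
            )
        return SmallAreaTrendResults(self, config, beta_ch, v_ch, vyr_ch, u_ch, sig_ch, mu_ch, ll_ch)

    def _run_chain(self, rng, config, chain, beta_ch, v_ch, vyr_ch, u_ch, sig_ch, mu_ch, ll_ch):
        sp = self.spec
        X, z, d, st = self._X, self._z, self._d, self._st
        kappa, n_eff = self._kappa, self._n
        p = X.shape[1]
        Qrw_struct = _rw_prior_precision(N_YEARS, sp.rw_order)
        rw_df_per_series = N_YEARS - sp.rw_order

        # time-invariant design over the 112 domains, for the interweaving
        # move that resolves the beta <-> v confounding (see _sweep_moves)
        dom = self.cells.drop_duplicates("d").sort_values("d")
        W_cols = [j for j, name in enumerate(self.param_names) if name != "year_std"]
        W = build_design(dom.assign(year=YEARS[0])).to_numpy()[:, W_cols]
        z_grid = np.unique(self._z_full)
        dz = float(np.diff(np.sort(z_grid)).mean())  # standardized-year step

        # initialization: pooled-rate intercept, slight jitter across chains
        pooled = np.clip(self._y.sum() / self._n.sum(), 1e-4, 1 - 1e-4)
        beta = np.zeros(p)
        beta[0] = np.log(pooled / (1 - pooled))
        beta += rng.normal(0, 0.1, size=p)
        v = np.zeros(N_DOMAINS)
        v_yr = np.zeros(N_DOMAINS)
        u = np.zeros((N_SERIES, N_YEARS))
        sig_I = sig_S = sig_RW = 0.5

        ones = np.ones(N_YEARS)
        keep = 0
        total = config.burn_in + config.iterations
        for it in range(total):
            eta = X @ beta
            if sp.domain_intercept:
                eta = eta + v[d]
            if sp.domain_slope:
                eta = eta + z * v_yr[d]
            if sp.rw:
                eta = eta + u.ravel()[st]
            omega = pg_draw(n_eff, eta, rng)

            # beta block (exact conjugate given omega)
            rest = eta - X @ beta
            P = (X * omega[:, None]).T @ X + np.eye(p) / sp.beta_prior_var
            rhs = X.T @ (kappa - omega * rest)
            L = np.linalg.cholesky(P)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            xb = X @ beta
            if sp.domain_intercept:
                rest = xb + (z * v_yr[d] if sp.domain_slope else 0.0)
                if sp.rw:
                    rest = rest + u.ravel()[st]
                prec = np.bincount(d, weights=omega, minlength=N_DOMAINS) + 1.0 / sig_I**2
                lin = np.bincount(d, weights=kappa - omega * rest, minlength=N_DOMAINS)
                v = lin / prec + rng.standard_normal(N_DOMAINS) / np.sqrt(prec)

            if sp.domain_slope:
                rest = xb + (v[d] if sp.domain_intercept else 0.0)
                if sp.rw:
                    rest = rest + u.ravel()[st]
                prec = (
                    np.bincount(d, weights=omega * z**2, minlength=N_DOMAINS) + 1.0 / sig_S**2
                )
                lin = np.bincount(d, weights=z * (kappa - omega * rest), minlength=N_DOMAINS)
                v_yr = lin / prec + rng.standard_normal(N_DOMAINS) / np.sqrt(prec)

            if sp.rw:
                rest = xb
                if sp.domain_intercept:
                    rest = rest + v[d]
                if sp.domain_slope:
                    rest = rest + z * v_yr[d]
                lam = np.bincount(st, weights=omega, minlength=N_SERIES * N_YEARS)
                lin = np.bincount(
                    st, weights=kappa - omega * rest, minlength=N_SERIES * N_YEARS
                )
                lam = lam.reshape(N_SERIES, N_YEARS)
                lin = lin.reshape(N_SERIES, N_YEARS)
                Qs = Qrw_struct / sig_RW**2
                for s in range(N_SERIES):
                    T = Qs + np.diag(lam[s] + 1e-10)
                    Lc = np.linalg.cholesky(T)
                    mean = np.linalg.solve(Lc.T, np.linalg.solve(Lc, lin[s]))
                    x = mean + np.linalg.solve(Lc.T, rng.standard_normal(N_YEARS))
                    # condition on the sum-to-zero constraint
                    w1 = np.linalg.solve(Lc.T, np.linalg.solve(Lc, ones))
                    x = x - w1 * (x.sum() / w1.sum())
                    u[s] = x

            # scale parameters: slice sampling on log sigma
            hs = sp.sigma_prior_scale

            def _sig_logp(log_s, ssq, k):
                s_ = np.exp(log_s)
                return -k * log_s - 0.5 * ssq / s_**2 - 0.5 * s_**2 / hs**2 + log_s

            if sp.domain_intercept:
                sig_I = np.exp(
                    _slice_sample(
                        np.log(sig_I),
                        lambda ls: _sig_logp(ls, float(np.sum(v**2)), N_DOMAINS),
                        rng,
                    )
                )
            if sp.domain_slope:
                sig_S = np.exp(
                    _slice_sample(
                        np.log(sig_S),
                        lambda ls: _sig_logp(ls, float(np.sum(v_yr**2)), N_DOMAINS),
                        rng,
                    )
                )
            if sp.rw:
                inc = np.diff(u, n=sp.rw_order, axis=1)
                sig_RW = np.exp(
                    _slice_sample(
                        np.log(sig_RW),
                        lambda ls: _sig_logp(
                            ls, float(np.sum(inc**2)), N_SERIES * rw_df_per_series
                        ),
                        rng,
                    )
                )

            # ASIS rescaling: re-draw each scale in the non-centered
            # parameterization (effects = sigma * standardized effects, the
            # standardized effects held fixed), which decorrelates the
            # scales from their effect vectors.
            xb = X @ beta
            if sp.domain_intercept and sig_I > 0:
                base = xb + (z * v_yr[d] if sp.domain_slope else 0.0)
                if sp.rw:
                    base = base + u.ravel()[st]
                vt = v / sig_I

                def _lp_I(ls):
                    s_ = np.exp(ls)
                    return float(self.loglik(base + s_ * vt[d]).sum()) - 0.5 * s_**2 / hs**2 + ls

                sig_I = np.exp(_slice_sample(np.log(sig_I), _lp_I, rng))
                v = sig_I * vt
            if sp.domain_slope and sig_S > 0:
                base = xb + (v[d] if sp.domain_intercept else 0.0)
                if sp.rw:
                    base = base + u.ravel()[st]
                vt = v_yr / sig_S

                def _lp_S(ls):
                    s_ = np.exp(ls)
                    return (
                        float(self.loglik(base + z * (s_ * vt[d])).sum()) - 0.5 * s_**2 / hs**2 + ls
                    )

                sig_S = np.exp(_slice_sample(np.log(sig_S), _lp_S, rng))
                v_yr = sig_S * vt
            if sp.rw and sig_RW > 0:
                base = xb
                if sp.domain_intercept:
                    base = base + v[d]
                if sp.domain_slope:
                    base = base + z * v_yr[d]
                ut = (u / sig_RW).ravel()

                def _lp_RW(ls):
                    s_ = np.exp(ls)
                    return (
                        float(self.loglik(base + s_ * ut[st]).sum()) - 0.5 * s_**2 / hs**2 + ls
                    )

                sig_RW = np.exp(_slice_sample(np.log(sig_RW), _lp_RW, rng))
                u = sig_RW * ut.reshape(N_SERIES, N_YEARS)

            # Interweaving (translation) moves: the likelihood is invariant
            # under (beta_tim + gamma, v - W gamma), (b_year + g, v_yr - g)
            # and (b_year + h, u - h * z); sampling gamma/g/h from their
            # exact Gaussian conditionals decorrelates fixed effects from
            # the random-effect means and makes the Gibbs chain mix.
            if sp.domain_intercept:
                Pg = W.T @ W / sig_I**2 + np.eye(W.shape[1]) / sp.beta_prior_var
                rg = W.T @ v / sig_I**2 - beta[W_cols] / sp.beta_prior_var
                Lg = np.linalg.cholesky(Pg)
                mg = np.linalg.solve(Lg.T, np.linalg.solve(Lg, rg))
                gamma = mg + np.linalg.solve(Lg.T, rng.standard_normal(W.shape[1]))
                beta[W_cols] += gamma
                v = v - W @ gamma
            if sp.domain_slope:
                pg_ = N_DOMAINS / sig_S**2 + 1.0 / sp.beta_prior_var
                mg = (v_yr.sum() / sig_S**2 - beta[1] / sp.beta_prior_var) / pg_
                g = mg + rng.standard_normal() / np.sqrt(pg_)
                beta[1] += g
                v_yr = v_yr - g
            if sp.rw and sp.rw_order == 1:
                # common linear trend of the RW series <-> year coefficient
                sum_du = float(u[:, -1].sum() - u[:, 0].sum())
                ph = N_SERIES * (N_YEARS - 1) * dz**2 / sig_RW**2 + 1.0 / sp.beta_prior_var
                mh = (dz * sum_du / sig_RW**2 - beta[1] / sp.beta_prior_var) / ph
                h = mh + rng.standard_normal() / np.sqrt(ph)
                beta[1] += h
                u = u - h * z_grid[None, :]
            if sp.rw and sp.rw_order == 1 and sp.domain_slope:
                # per-series trend of u <-> mean domain slope of its domains:
                # u_s + c_s z and v_yr_d - c_s (d in series s) leave the
                # likelihood invariant; c_s has a Gaussian conditional from
                # the two priors.
                dom_series = self._dom_series
                n_per = self._n_dom_per_series
                sum_vyr = np.bincount(dom_series, weights=v_yr, minlength=N_SERIES)
                du = u[:, -1] - u[:, 0]
                Pc = n_per / sig_S**2 + (N_YEARS - 1) * dz**2 / sig_RW**2
                mc = (sum_vyr / sig_S**2 - dz * du / sig_RW**2) / Pc
                c = mc + rng.standard_normal(N_SERIES) / np.sqrt(Pc)
                v_yr = v_yr - c[dom_series]
                u = u + c[:, None] * z_grid[None, :]

            if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
                beta_ch[chain, keep] = beta
                if v_ch is not None:
                    v_ch[chain, keep] = v
                if vyr_ch is not None:
                    vyr_ch[chain, keep] = v_yr
                if u_ch is not None:
                    u_ch[chain, keep] = u
                sig_ch[chain, keep] = (sig_I, sig_S, sig_RW)
                eta_full = self.linear_predictor(
                    beta,
                    v if sp.domain_intercept else None,
                    v_yr if sp.domain_slope else None,
                    u if sp.rw else None,
                    full=True,
                )
                # clamp so stored float32 prevalences stay strictly inside (0,1)
                mu_ch[chain, keep] = np.clip(
                    expit(eta_full).astype(np.float32), 1e-7, 1.0 - 1e-7
                )
                eta_obs = self.linear_predictor(
                    beta,
                    v if sp.domain_intercept else None,
                    v_yr if sp.domain_slope else None,
                    u if sp.rw else None,
                )
                ll_ch[chain, keep] = self.loglik(eta_obs)
                keep += 1


def rhat_ess(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-chain R-hat and effective sample size per scalar parameter.

    ``sample`` has shape (chains, draws) or (chains, draws, k). Requires at
    least 2 chains (R-hat is undefined otherwise).
    """
    import arviz as az

    sample = np.asarray(sample)
    if sample.ndim == 2:
        sample = sample[:, :, None]
    if sample.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    ds = az.convert_to_dataset(sample)
    rh = np.atleast_1d(np.asarray(az.rhat(ds)["x"])).ravel()
    es = np.atleast_1d(np.asarray(az.ess(ds)["x"])).ravel()
    return rh, es


def fit_mcmc(
    data: pd.DataFrame, spec: ModelSpec | None = None, config: McmcConfig | None = None
) -> "SmallAreaTrendResults":
    """Functional wrapper: build the model from direct estimates and fit."""
    return SmallAreaTrendModel(data, spec).fit(config)


class SmallAreaTrendResults:
    """Posterior draws, diagnostics and predictions of a fitted model.

    Attributes
    ----------
    draws : dict of chain-major arrays ``(chains, kept, ...)`` for ``beta``,
        ``v``, ``v_yr``, ``u`` and ``sigma`` (columns sigma_I, sigma_S,
        sigma_RW).
    mu_draws : (chains*kept, 2352) posterior prevalence draws for every
        domain-year cell, survey or not.
    log_likelihood : (chains*kept, n_obs) per-observation log-likelihood.
    converged : all monitored R-hat < 1.1 (None for a single chain).
    """

    RHAT_THRESHOLD = 1.1

    def __init__(self, model, config, beta, v, v_yr, u, sigma, mu, loglik):
        self.model = model
        self.config = config
        self.draws = {"beta": beta, "sigma": sigma}
        if v is not None:
            self.draws["v"] = v
        if v_yr is not None:
            self.draws["v_yr"] = v_yr
        if u is not None:
            self.draws["u"] = u
        self.mu_draws = mu.reshape(-1, mu.shape[-1])
        self.log_likelihood = loglik.reshape(-1, loglik.shape[-1])
        self._loglik_chains = loglik
        self._diag = None

        if config.chains >= 2:
            self._diag = self._compute_diagnostics()
            self.max_rhat = float(self._diag["rhat"].max())
            self.converged = bool(self.max_rhat < self.RHAT_THRESHOLD)
            if not self.converged:
                logger.warning(
                    "MCMC not converged: max R-hat %.3f >= %.2f", self.max_rhat, self.RHAT_THRESHOLD
                )
        else:
            logger.warning("single chain: R-hat undefined")
            self.max_rhat = float("nan")
            self.converged = None

    @property
    def n_draws(self) -> int:
        return self.mu_draws.shape[0]

    # -- diagnostics -----------------------------------------------------------

    def _compute_diagnostics(self) -> pd.DataFrame:
        rows = []
        sig_names = ["sigma_I", "sigma_S", "sigma_RW"]
        for name, arr in self.draws.items():
            a = arr.reshape(arr.shape[0], arr.shape[1], -1)
            rh, es = rhat_ess(a)
            for j in range(a.shape[2]):
                if name == "beta":
                    label = self.model.param_names[j]
                elif name == "sigma":
                    label = sig_names[j]
                else:
                    label = f"{name}[{j}]"
                rows.append({"parameter": label, "rhat": rh[j], "ess": es[j]})
        return pd.DataFrame(rows)

    def diagnostics(self) -> pd.DataFrame:
        """R-hat and effective sample size per scalar parameter."""
        if self._diag is None:
            return pd.DataFrame(
                {
                    "parameter": self.model.param_names,
                    "rhat": np.nan,
                    "ess": np.nan,
                }
            )
        return self._diag.copy()

    # -- summaries -------------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary of fixed effects and variance parameters.

        ``mean`` and ``sd`` are across all retained draws; ``t_value`` is
        mean/sd (|t| > 1.96 flags a clearly nonzero coefficient).
        """
        beta = self.draws["beta"].reshape(-1, len(self.model.param_names))
        rows = []
        diag = self.diagnostics().set_index("parameter")
        for j, name in enumerate(self.model.param_names):
            m, s = beta[:, j].mean(), beta[:, j].std(ddof=1)
            rows.append(
                {
                    "parameter": name,
                    "mean": m,
                    "sd": s,
                    "t_value": m / s if s > 0 else np.nan,
                    "rhat": diag["rhat"].get(name, np.nan),
                }
            )
        sig = self.draws["sigma"].reshape(-1, 3)
        for j, name in enumerate(["sigma2_I", "sigma2_S", "sigma2_RW1"]):
            var_draws = sig[:, j] ** 2
            m, s = var_draws.mean(), var_draws.std(ddof=1)
            rows.append(
                {
                    "parameter": name,
                    "mean": m,
                    "sd": s,
                    "t_value": m / s if s > 0 else np.nan,
                    "rhat": diag["rhat"].get(name.replace("sigma2", "sigma").replace("_RW1", "_RW"), np.nan),
                }
            )
        return pd.DataFrame(rows)

    def predict_prevalence(self) -> pd.DataFrame:
        """Posterior trend for all 2352 domain-year cells.

        Point estimate = posterior mean, se = posterior SD, and equal-tailed
        central 95% interval, per cell. Zero-sample and non-survey cells are
        predicted like any other.
        """
        mu = self.mu_draws.astype(float)
        out = self.model.cells[["state", "age_group", "sex", "year"]].copy()
        out["est"] = mu.mean(axis=0)
        out["se"] = mu.std(axis=0, ddof=1)
        lo, hi = np.percentile(mu, [2.5, 97.5], axis=0)
        out["lo95"] = lo
        out["hi95"] = hi
        return out

    def aggregate(self, population: pd.DataFrame, level: str) -> pd.DataFrame:
        """Population-weighted aggregation of the prevalence draws."""
        from smalltrend.aggregate import aggregate_draws

        return aggregate_draws(self.mu_draws, self.model.cells, population, level)

    def to_npz(self, path) -> None:
        """Persist draws in a documented name -> array container."""
        payload = {k: v for k, v in self.draws.items()}
        payload["mu"] = self.mu_draws
        payload["log_likelihood"] = self.log_likelihood
        np.savez_compressed(path, **payload)
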