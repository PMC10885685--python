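"""Synthetic survey generator.

Everything downstream is testable without restricted micro-data: this module
draws a true prevalence surface from the same generative model that the
package later fits (logit-linear trend with domain random intercepts/slopes
and sex-by-age RW1 temporal effects), builds an estimated-resident-population
analogue, and simulates stratified multistage survey waves with unequal
selection probabilities, calibration weights and delete-a-group jackknife
replicate weights.

The generator's defaults emulate the national health survey setting: 112
state-age-sex domains, seven waves over 2001-2021, roughly 15000 adult
respondents per wave, the smallest territory sparsely sampled, and domains
with structurally zero sample (adults 70+ in NT).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from smalltrend.design import beta_vector, build_design
from smalltrend.domains import (
    AGE_GROUPS,
    DEFAULT_SURVEY_YEARS,
    N_DOMAINS,
    N_YEARS,
    SEXES,
    SEX_AGE_CELLS,
    STATES,
    YEARS,
    cell_table,
    check_survey_years,
    domain_table,
)

logger = logging.getLogger(__name__)

#: Default generating fixed effects: a declining national trend from roughly
#: 24% to 12% prevalence over the 21-year window, higher prevalence for
#: males, lower for the oldest ages, and moderate state contrasts.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -2.03,
    "year_std": -0.23,
    "male": 0.24,
    "age:25-29": 0.20,
    "age:30-39": 0.15,
    "age:40-49": 0.19,
    "age:50-59": 0.07,
    "age:60-69": -0.35,
    "age:70+": -1.21,
    "state:NSW": 0.26,
    "state:VIC": 0.25,
    "state:QLD": 0.38,
    "state:SA": 0.31,
    "state:WA": 0.22,
    "state:TAS": 0.52,
    "state:NT": 0.65,
    "male:age:25-29": 0.19,
    "male:age:30-39": 0.20,
    "male:age:40-49": 0.06,
    "male:age:50-59": 0.04,
    "male:age:60-69": -0.04,
    "male:age:70+": 0.03,
}


@dataclass
class TruthParams:
    """Generating parameters of the truth surface.

    ``beta`` maps fixed-effect column names (see
    :func:`smalltrend.design.design_columns`) to coefficients; missing names
    default to 0. The three variances drive the domain random intercept, the
    domain random slope on standardized year, and the RW1 innovation.
    """

    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma2_intercept: float = 0.04
    sigma2_slope: float = 0.04
    sigma2_rw1: float = 0.07

    def validate(self) -> None:
        for name in ("sigma2_intercept", "sigma2_slope", "sigma2_rw1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite nonnegative number, got {v!r}")
        beta_vector(self.beta)  # raises on unknown names


@dataclass
class TruthSurface:
    """True prevalence for every domain-year cell.

    ``mu`` is (112, 21) over (domain index d, year index t); ``year0`` is
    the calendar year of t=0. The realized random effects are retained so
    the linear predictor can be reconstructed exactly.
    """

    mu: np.ndarray
    params: TruthParams
    v_intercept: np.ndarray  # (112,)
    v_slope: np.ndarray  # (112,)
    u_rw1: np.ndarray  # (14, 21), sum-to-zero over t per sex-age series
    year0: int = YEARS[0]

    def as_frame(self) -> pd.DataFrame:
        cells = cell_table()
        t_idx = cells["year"].to_numpy() - self.year0
        cells = cells[["state", "age_group", "sex", "year"]].copy()
        cells["mu"] = self.mu[cell_table()["d"].to_numpy(), t_idx]
        return cells


def draw_truth(params: TruthParams | None = None, seed: int = 0) -> TruthSurface:
    """Draw a true prevalence surface from the generative model.

    ``logit(mu_dt) = beta' x_dt + v_d + z_t v_d^yr + u_t^(sex-age)`` with
    ``v_d ~ N(0, sigma2_intercept)``, ``v_d^yr ~ N(0, sigma2_slope)``
    independent, and ``u`` a first-order random walk per sex-by-age cell
    with innovation variance ``sigma2_rw1``, identified by a sum-to-zero
    constraint over the 21 years (its level is carried by the fixed
    effects; centering leaves first differences untouched).
    """
    params = params or TruthParams()
    params.validate()
    rng = np.random.default_rng(seed)

    v_int = rng.normal(0.0, np.sqrt(params.sigma2_intercept), size=N_DOMAINS)
    v_slo = rng.normal(0.0, np.sqrt(params.sigma2_slope), size=N_DOMAINS)
    innov = rng.normal(0.0, np.sqrt(params.sigma2_rw1), size=(len(SEX_AGE_CELLS), N_YEARS - 1))
    u = np.concatenate([np.zeros((len(SEX_AGE_CELLS), 1)), np.cumsum(innov, axis=1)], axis=1)
    u -= u.mean(axis=1, keepdims=True)

    cells = cell_table()
    X = build_design(cells).to_numpy()
    b = beta_vector(params.beta)
    z = X[:, 1]  # standardized year column
    d = cells["d"].to_numpy()
    t = cells["year"].to_numpy() - YEARS[0]
    s = cells["sex_age"].to_numpy()
    eta = X @ b + v_int[d] + z * v_slo[d] + u[s, t]
    mu = np.empty((N_DOMAINS, N_YEARS))
    mu[d, t] = 1.0 / (1.0 + np.exp(-eta))
    return TruthSurface(mu=mu, params=params, v_intercept=v_int, v_slope=v_slo, u_rw1=u)


# ---------------------------------------------------------------------------
# Population (estimated-resident-population analogue)
# ---------------------------------------------------------------------------

#: Approximate adult population shares by state, largest to smallest; NT is
#: deliberately the smallest so its domains are sparse downstream.
DEFAULT_STATE_SHARES: dict[str, float] = {
    "NSW": 0.320,
    "VIC": 0.258,
    "QLD": 0.199,
    "WA": 0.104,
    "SA": 0.072,
    "TAS": 0.021,
    "ACT": 0.017,
    "NT": 0.009,
}

DEFAULT_AGE_SHARES: dict[str, float] = {
    "18-24": 0.117,
    "25-29": 0.092,
    "30-39": 0.180,
    "40-49": 0.172,
    "50-59": 0.160,
    "60-69": 0.140,
    "70+": 0.139,
}


@dataclass
class PopulationConfig:
    """Controls for the synthetic domain-by-year population table."""

    total_adults: float = 19_000_000.0
    state_shares: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_SHARES))
    age_shares: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_SHARES))
    male_share: float = 0.494
    annual_growth: float = 0.013
    jitter_sd: float = 0.02  # lognormal sd of multiplicative cell noise

    def validate(self) -> None:
        if self.total_adults <= 0:
            raise ValueError("total_adults must be positive")
        for name, keys in (("state_shares", STATES), ("age_shares", AGE_GROUPS)):
            shares = getattr(self, name)
            missing = set(keys) - set(shares)
            if missing:
                raise ValueError(f"{name} missing levels {sorted(missing)}")
            if any(v <= 0 for v in shares.values()):
                raise ValueError(f"{name} must be strictly positive (zero state total rejected)")
        if not 0 < self.male_share < 1:
            raise ValueError("male_share must be in (0,1)")


def make_population(config: PopulationConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Build the complete 112 x 21 population table.

    Counts are ``total x state share x age share x sex share`` compounded by
    annual growth relative to the mid-window year, with a small lognormal
    cell jitter; deterministic under ``seed``. Returns columns
    (state, age_group, sex, year, pop) over all 2352 cells.
    """
    config = config or PopulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    cells = cell_table()
    st = cells["state"].map(config.state_shares).to_numpy()
    ag = cells["age_group"].map(config.age_shares).to_numpy()
    sx = np.where(cells["sex"] == "male", config.male_share, 1 - config.male_share)
    growth = (1 + config.annual_growth) ** (cells["year"].to_numpy() - np.mean(YEARS))
    base = config.total_adults * st * ag * sx * growth
    if config.jitter_sd > 0:
        base = base * rng.lognormal(0.0, config.jitter_sd, size=len(base))
    out = cells[["state", "age_group", "sex", "year"]].copy()
    out["pop"] = np.rint(base).astype(np.int64)
    if (out.groupby("state")["pop"].sum() <= 0).any():
        raise ValueError("zero total population for a state")
    return out


# ---------------------------------------------------------------------------
# Survey design and wave simulation
# ---------------------------------------------------------------------------


#: Selected clusters per state stratum. With ~30 dwellings sampled per
#: cluster and an 85% response rate this yields roughly 15000 adult
#: respondents per wave, allocated so the small territories are sparse
#: (NT of the order of a few hundred respondents), as in national
#: health-survey practice.
DEFAULT_CLUSTERS_PER_STRATUM: dict[str, int] = {
    "NSW": 170,
    "VIC": 140,
    "QLD": 110,
    "WA": 70,
    "SA": 55,
    "TAS": 25,
    "ACT": 20,
    "NT": 18,
}


@dataclass
class DesignConfig:
    """Stratified multistage sampling design for one synthetic survey.

    Strata are states; within each stratum, clusters (area units counted in
    dwellings) are selected with probability proportional to size, dwellings
    within clusters by systematic random sampling, and one adult per
    dwelling with probability inversely proportional to the number of adults
    in it. ``zero_sample_domains`` lists (state, age_group, sex) cells —
    ``None`` is a wildcard — that receive no respondents, deterministically.
    """

    survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS
    clusters_per_stratum: int | dict = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS_PER_STRATUM)
    )
    frame_clusters_per_stratum: int = 900
    dwellings_per_cluster: int = 120
    n_replicates: int = 60
    #: per-wave override of the replicate-group count (the first round used
    #: 30 replicate weights, later rounds 60)
    n_replicates_by_year: dict = field(default_factory=lambda: {2001: 30})
    #: per-wave multiplier on cluster counts, emulating the uneven achieved
    #: sample sizes of the seven rounds (largest in 2005, a markedly smaller
    #: final wave); 1.0 for years not listed.
    wave_cluster_scale: dict = field(
        default_factory=lambda: {
            2001: 1.16,
            2005: 1.34,
            2008: 1.02,
            2012: 1.00,
            2015: 0.94,
            2018: 1.06,
            2021: 0.65,
        }
    )
    #: female:male participation ratio (females overrepresented ~10%)
    female_participation_ratio: float = 1.1
    response_rate: float = 0.85
    calibration_tol: float = 1e-6
    zero_sample_domains: tuple[tuple[str | None, str | None, str | None], ...] = (
        ("NT", "70+", None),
    )
    census: bool = False
    seed: int = 0

    def validate(self) -> None:
        check_survey_years(self.survey_years)
        if self.n_replicates < 2:
            raise ValueError("n_replicates (R) must be >= 2")
        for state in STATES:
            if self.clusters_for(state) < 1:
                raise ValueError("at least 1 cluster per stratum")
        if not 0 < self.response_rate <= 1:
            raise ValueError("response_rate must be in (0,1]")

    def replicates_for(self, year: int) -> int:
        return int(self.n_replicates_by_year.get(year, self.n_replicates))

    def clusters_for(self, state: str) -> int:
        c = self.clusters_per_stratum
        if isinstance(c, dict):
            if state not in c:
                raise ValueError(f"clusters_per_stratum missing state {state!r}")
            return int(c[state])
        return int(c)


def _excluded_mask(cells: pd.DataFrame, zero_list) -> np.ndarray:
    mask = np.zeros(len(cells), dtype=bool)
    for state, age, sex in zero_list:
        m = np.ones(len(cells), dtype=bool)
        if state is not None:
            m &= (cells["state"] == state).to_numpy()
        if age is not None:
            m &= (cells["age_group"] == age).to_numpy()
        if sex is not None:
            m &= (cells["sex"] == sex).to_numpy()
        mask |= m
    return mask


def pps_inclusion_probabilities(sizes: np.ndarray, n: int) -> np.ndarray:
    """First-order inclusion probabilities of without-replacement PPS.

    Units with ``n * size / total >= 1`` are take-all certainties; the
    remainder receive ``n' * size / total'`` after removing certainties,
    iterated to a fixed point.
    """
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("cluster sizes must be positive")
    pi = np.ones_like(sizes)
    certain = np.zeros(len(sizes), dtype=bool)
    while True:
        m = n - certain.sum()
        rest = ~certain
        if m <= 0 or not rest.any():
            break
        p = m * sizes[rest] / sizes[rest].sum()
        newly = np.zeros_like(certain)
        newly[rest] = p >= 1.0
        if not newly.any():
            pi[rest] = p
            break
        certain |= newly
    pi[certain] = 1.0
    return pi


def systematic_pps(sizes: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic PPS on a randomly ordered frame; returns selected indices.

    The random ordering makes every unit's realized inclusion probability
    equal to the nominal :func:`pps_inclusion_probabilities` value.
    """
    sizes = np.asarray(sizes, dtype=float)
    pi = pps_inclusion_probabilities(sizes, n)
    certain = np.flatnonzero(pi >= 1.0)
    rest = np.flatnonzero(pi < 1.0)
    m = n - len(certain)
    if m <= 0:
        return certain
    order = rng.permutation(rest)
    p = pi[order]
    cum = np.cumsum(p)
    start = rng.uniform(0, 1)
    points = start + np.arange(m)
    chosen = order[np.searchsorted(cum, points)]
    return np.concatenate([certain, chosen])


def simulate_wave(
    truth: TruthSurface,
    population: pd.DataFrame,
    design: DesignConfig,
    year: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one survey wave, returning the person-level table.

    Columns: person_id, year, state, age_group, sex, smoker, weight. Base
    weights are inverse inclusion probabilities adjusted for nonresponse and
    calibrated so that within each state they sum to the in-scope adult
    population. Replicate-weight columns are added separately by
    :func:`make_replicate_weights`.
    """
    design.validate()
    if year not in design.survey_years:
        raise ValueError(f"{year} is not a survey wave of this design")
    rng = np.random.default_rng(design.seed + 1000 * year if seed is None else seed)

    pop_y = population[population["year"] == year].copy()
    if len(pop_y) != N_DOMAINS:
        raise ValueError(f"population table must cover all {N_DOMAINS} domains for {year}")
    excluded = _excluded_mask(pop_y, design.zero_sample_domains)
    pop_y = pop_y.loc[~excluded]
    d_idx = pop_y.pipe(_domain_idx)
    t_idx = year - truth.year0
    mu_dom = truth.mu[d_idx, t_idx]

    if design.census:
        return _census_wave(pop_y, mu_dom, year, rng)

    frames = []
    pid0 = 0
    for state in STATES:
        sub = pop_y[pop_y["state"] == state]
        if sub.empty:
            continue
        state_pop = float(sub["pop"].sum())
        tilt = np.where(
            sub["sex"].to_numpy() == "female", design.female_participation_ratio, 1.0
        )
        dom_p = sub["pop"].to_numpy() * tilt
        dom_p = dom_p / dom_p.sum()
        mu_sub = mu_dom[(pop_y["state"] == state).to_numpy()]

        n_frame = design.frame_clusters_per_stratum
        sizes = rng.gamma(8.0, design.dwellings_per_cluster / 8.0, size=n_frame)
        sizes = np.maximum(sizes, 2.0)
        scale = design.wave_cluster_scale.get(year, 1.0)
        n_sel = min(max(2, int(round(design.clusters_for(state) * scale))), n_frame)
        sel = systematic_pps(sizes, n_sel, rng)
        pi_cl = pps_inclusion_probabilities(sizes, n_sel)

        m_dw = max(4, design.dwellings_per_cluster // 4)  # dwellings sampled per cluster
        rows_state = []
        for ci in sel:
            s_i = sizes[ci]
            m_i = min(m_dw, int(np.floor(s_i)))
            pi_dw = m_i / s_i
            # one adult per dwelling; 1-3 adults per dwelling
            h = rng.choice([1, 2, 3], size=m_i, p=[0.35, 0.45, 0.20])
            resp = rng.uniform(size=m_i) < design.response_rate
            n_resp = int(resp.sum())
            if n_resp == 0:
                continue
            h = h[resp]
            dom = rng.choice(len(sub), size=n_resp, p=dom_p)
            w = h / (pi_cl[ci] * pi_dw)
            rows_state.append(
                pd.DataFrame(
                    {
                        "cluster": ci,
                        "state": state,
                        "age_group": sub["age_group"].to_numpy()[dom],
                        "sex": sub["sex"].to_numpy()[dom],
                        "smoker": (rng.uniform(size=n_resp) < mu_sub[dom]).astype(np.int64),
                        "weight": w,
                    }
                )
            )
        if not rows_state:
            continue
        df_state = pd.concat(rows_state, ignore_index=True)
        # nonresponse-adjusted weights are calibrated to the in-scope state total
        df_state["weight"] *= state_pop / df_state["weight"].sum()
        frames.append(df_state)
        pid0 += len(df_state)

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "person_id", np.arange(len(out)))
    out.insert(1, "year", year)
    return out


def _domain_idx(df: pd.DataFrame) -> np.ndarray:
    from smalltrend.domains import domain_index

    return domain_index(df)


def _census_wave(pop_y, mu_dom, year, rng):
    """Full enumeration: every in-scope adult observed with weight 1."""
    counts = pop_y["pop"].to_numpy().astype(int)
    reps = np.repeat(np.arange(len(pop_y)), counts)
    n = len(reps)
    out = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "year": year,
            "cluster": np.repeat(np.arange(len(pop_y)), counts),  # one cluster per domain
            "state": pop_y["state"].to_numpy()[reps],
            "age_group": pop_y["age_group"].to_numpy()[reps],
            "sex": pop_y["sex"].to_numpy()[reps],
            "smoker": (rng.uniform(size=n) < np.repeat(mu_dom, counts)).astype(np.int64),
            "weight": 1.0,
        }
    )
    return out


def make_replicate_weights(sample: pd.DataFrame, R: int, seed: int = 0) -> pd.DataFrame:
    """Attach R delete-a-group jackknife replicate-weight columns.

    Within each stratum (state) the wave's clusters are randomly partitioned
    into R groups; replicate c zeroes the weights of group-c clusters and
    rescales the remaining clusters of the same stratum by R/(R-1). Strata
    with fewer clusters than R fall back to person-level grouping (logged).
    Adds columns ``rw_1 .. rw_R``.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    if "weight" not in sample.columns:
        raise ValueError("sample must carry base weights")
    rng = np.random.default_rng(seed)
    out = sample.copy()
    group = np.empty(len(out), dtype=int)
    for state, idx in out.groupby("state", sort=False).indices.items():
        clusters = out["cluster"].to_numpy()[idx]
        uniq = pd.unique(clusters)
        if len(uniq) >= R:
            g_of = dict(zip(uniq, rng.permutation(np.arange(len(uniq)) % R)))
            group[idx] = [g_of[c] for c in clusters]
        else:
            msg = (
                f"stratum {state}: {len(uniq)} clusters < R={R}; "
                "falling back to person-level jackknife groups"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            group[idx] = rng.permutation(np.arange(len(idx)) % R)
    w = out["weight"].to_numpy()
    factor = R / (R - 1.0)
    rw = np.where(group[:, None] == np.arange(R)[None, :], 0.0, w[:, None] * factor)
    for c in range(R):
        out[f"rw_{c + 1}"] = rw[:, c]
    return out


def simulate_survey(
    params: TruthParams | None = None,
    design: DesignConfig | None = None,
    pop_config: PopulationConfig | None = None,
    seed: int = 0,
) -> dict:
    """End-to-end generation: truth, population, and all survey waves.

    Returns a dict with keys ``truth`` (:class:`TruthSurface`),
    ``population`` (DataFrame) and ``waves`` (year -> person-level DataFrame
    with replicate weights).
    """
    design = replace(design or DesignConfig(), seed=seed)
    truth = draw_truth(params, seed=seed)
    population = make_population(pop_config, seed=seed + 1)
    waves = {}
    for i, year in enumerate(check_survey_years(design.survey_years)):
        wave = simulate_wave(truth, population, design, year, seed=seed + 7919 * (i + 1))
        waves[year] = make_replicate_weights(
            wave, design.replicates_for(year), seed=seed + 104729 * (i + 1)
        )
    return {"truth": truth, "population": population, "waves": waves}


# ---------------------------------------------------------------------------
# CSV writers (documented external schemas)
# ---------------------------------------------------------------------------


def write_population_csv(population: pd.DataFrame, path) -> None:
    population[["state", "age_group", "sex", "year", "pop"]].to_csv(path, index=False)


def write_truth_csv(truth: TruthSurface, path) -> None:
    truth.as_frame().to_csv(path, index=False)


def write_survey_csv(wave: pd.DataFrame, path) -> None:
    cols = ["person_id", "year", "state", "age_group", "sex", "smoker", "weight"]
    cols += [c for c in wave.columns if c.startswith("rw_")]
    wave[cols].to_csv(path, index=False)
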