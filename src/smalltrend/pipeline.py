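"""File-based pipeline orchestration.

Stages communicate only through documented CSV/JSON/NPZ artifacts in the
run directory, so any stage can be re-run, swapped or tested in isolation:

    simulate  -> population.csv, truth.csv, survey_<year>.csv
    direct    -> direct_estimates.csv
    fit       -> draws.npz, trend_detailed.csv, diagnostics.csv
    aggregate -> trend_<level>.csv
    assess    -> fit_criteria.json, ppc.csv, cv_comparison.csv
    joinpoint -> joinpoint_results.csv
    report    -> report/*.png, report/report.md

All randomness flows from the single master seed in the config; per-stage
seeds are derived deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from smalltrend import __version__
from smalltrend.aggregate import aggregate_direct, aggregate_draws, benchmark
from smalltrend.assessment import compare_cv, fit_criteria, posterior_predictive_check
from smalltrend.config import RunConfig
from smalltrend.direct import direct_estimates, write_direct_csv
from smalltrend.domains import cell_table
from smalltrend.joinpoint import batch_joinpoint
from smalltrend.model import SmallAreaTrendModel
from smalltrend.synthetic import (
    draw_truth,
    make_population,
    make_replicate_weights,
    simulate_wave,
    write_population_csv,
    write_survey_csv,
    write_truth_csv,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "direct", "fit", "aggregate", "assess", "joinpoint", "report")

_PRODUCERS = {
    "population.csv": "simulate",
    "truth.csv": "simulate",
    "direct_estimates.csv": "direct",
    "draws.npz": "fit",
    "trend_detailed.csv": "fit",
    "diagnostics.csv": "fit",
    "trend_national.csv": "aggregate",
    "joinpoint_results.csv": "joinpoint",
}


class MissingArtifactError(FileNotFoundError):
    def __init__(self, artifact: str):
        stage = _PRODUCERS.get(artifact, "an earlier stage")
        super().__init__(
            f"missing artifact {artifact!r}; run the {stage!r} stage first"
        )


def _need(out: Path, name: str) -> Path:
    p = out / name
    if not p.exists():
        raise MissingArtifactError(name)
    return p


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_stage(name: str, cfg: RunConfig) -> list[Path]:
    """Run one pipeline stage; returns the artifact paths written."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info(
        "stage %s: package %s, seed %d, config hash %s", name, __version__, cfg.seed, _config_hash(cfg)
    )
    artifacts = globals()[f"_stage_{name}"](cfg, out)
    logger.info("stage %s finished in %.1f s", name, time.time() - t0)
    return artifacts


def run_all(cfg: RunConfig) -> list[Path]:
    arts = []
    for stage in STAGES:
        arts += run_stage(stage, cfg)
    return arts


# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    truth = draw_truth(cfg.truth, seed=cfg.seed)
    population = make_population(cfg.population, seed=cfg.seed + 1)
    paths = [out / "population.csv", out / "truth.csv"]
    write_population_csv(population, paths[0])
    write_truth_csv(truth, paths[1])
    design = cfg.design
    for i, year in enumerate(sorted(design.survey_years)):
        wave = simulate_wave(truth, population, design, year, seed=cfg.seed + 7919 * (i + 1))
        wave = make_replicate_weights(
            wave, design.replicates_for(year), seed=cfg.seed + 104729 * (i + 1)
        )
        p = out / f"survey_{year}.csv"
        write_survey_csv(wave, p)
        paths.append(p)
    return paths


def _stage_direct(cfg: RunConfig, out: Path) -> list[Path]:
    waves = {}
    for year in sorted(cfg.design.survey_years):
        p = _need(out, f"survey_{year}.csv")
        waves[year] = pd.read_csv(p)
    est = direct_estimates(waves)
    path = out / "direct_estimates.csv"
    write_direct_csv(est, path)
    return [path]


def _stage_fit(cfg: RunConfig, out: Path) -> list[Path]:
    est = pd.read_csv(_need(out, "direct_estimates.csv"))
    model = SmallAreaTrendModel(est, cfg.model)
    res = model.fit(cfg.mcmc)
    res.to_npz(out / "draws.npz")
    res.predict_prevalence().to_csv(out / "trend_detailed.csv", index=False)
    res.diagnostics().to_csv(out / "diagnostics.csv", index=False)
    return [out / "draws.npz", out / "trend_detailed.csv", out / "diagnostics.csv"]


def _load_mu(out: Path) -> np.ndarray:
    with np.load(_need(out, "draws.npz")) as z:
        return z["mu"].astype(float)


def _stage_aggregate(cfg: RunConfig, out: Path) -> list[Path]:
    mu = _load_mu(out)
    population = pd.read_csv(_need(out, "population.csv"))
    cells = cell_table()
    paths = []
    for level in cfg.joinpoint.levels:
        tr = aggregate_draws(mu, cells, population, level)
        p = out / f"trend_{level}.csv"
        tr.to_csv(p, index=False)
        paths.append(p)
    return paths


def _stage_assess(cfg: RunConfig, out: Path) -> list[Path]:
    est = pd.read_csv(_need(out, "direct_estimates.csv"))
    with np.load(_need(out, "draws.npz")) as z:
        mu = z["mu"].astype(float)
        ll = z["log_likelihood"]

    model = SmallAreaTrendModel(est, cfg.model)
    shim = _LoadedResults(model, mu, ll)

    # criteria: log-lik at the posterior-mean prevalence of observed cells
    from smalltrend.assessment import _observed_cell_columns

    obs_cols = _observed_cell_columns(model)
    mu_bar = mu[:, obs_cols].mean(axis=0)
    eta_bar = np.log(mu_bar / (1 - mu_bar))
    crit = fit_criteria(ll, model.loglik(eta_bar))
    (out / "fit_criteria.json").write_text(json.dumps(crit, indent=2))

    ppc = pd.concat(
        [
            posterior_predictive_check(shim, stat, seed=cfg.seed + 17)
            for stat in ("year_mean", "domain_max", "zero_cells")
        ],
        ignore_index=True,
    )
    ppc.to_csv(out / "ppc.csv", index=False)

    trend = pd.read_csv(_need(out, "trend_detailed.csv"))
    cv = compare_cv(trend, est)
    cv["per_year"].to_csv(out / "cv_comparison.csv", index=False)
    return [out / "fit_criteria.json", out / "ppc.csv", out / "cv_comparison.csv"]


class _LoadedResults:
    """Minimal results view reconstructed from pipeline artifacts."""

    def __init__(self, model, mu_draws, log_likelihood):
        self.model = model
        self.mu_draws = mu_draws
        self.log_likelihood = log_likelihood
        self.n_draws = mu_draws.shape[0]


def _stage_joinpoint(cfg: RunConfig, out: Path) -> list[Path]:
    frames = []
    for level in cfg.joinpoint.levels:
        frames.append(pd.read_csv(_need(out, f"trend_{level}.csv")))
    if cfg.joinpoint.detailed:
        mu = _load_mu(out)
        population = pd.read_csv(_need(out, "population.csv"))
        frames.append(aggregate_draws(mu, cell_table(), population, "detailed"))
    trends = pd.concat(frames, ignore_index=True)
    jp = cfg.joinpoint
    res = batch_joinpoint(trends, k_max=jp.k_max, alpha=jp.alpha, n_perm=jp.n_perm, seed=cfg.seed + 23)
    res.to_csv(out / "joinpoint_results.csv", index=False)
    return [out / "joinpoint_results.csv"]


def _stage_report(cfg: RunConfig, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = out / "report"
    rep.mkdir(exist_ok=True)
    paths = []

    # trend panels: national + states, then ages
    trend_nat = pd.read_csv(_need(out, "trend_national.csv"))
    direct = pd.read_csv(_need(out, "direct_estimates.csv"))
    population = pd.read_csv(_need(out, "population.csv"))

    def _panels(levels, fname, ncols=3):
        frames = [pd.read_csv(_need(out, f"trend_{lv}.csv")) for lv in levels]
        tr = pd.concat(frames, ignore_index=True)
        series = list(tr.groupby(["level", "cell"]).groups)
        n = len(series)
        nrows = int(np.ceil(n / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.8 * nrows), squeeze=False)
        for ax, (level, cell) in zip(axes.ravel(), series):
            g = tr[(tr["level"] == level) & (tr["cell"] == cell)].sort_values("year")
            ax.plot(g["year"], 100 * g["est"], color="C0")
            ax.fill_between(g["year"], 100 * g["lo95"], 100 * g["hi95"], alpha=0.25, color="C0")
            da = aggregate_direct(direct, population, level)
            da = da[da["cell"] == cell]
            ax.errorbar(
                da["year"], 100 * da["est"], yerr=100 * 1.96 * da["se"], fmt="o", ms=3, color="C3"
            )
            ax.set_title(f"{level}: {cell}", fontsize=9)
            ax.set_ylabel("prevalence (%)")
        for ax in axes.ravel()[n:]:
            ax.axis("off")
        fig.tight_layout()
        p = rep / fname
        fig.savefig(p, dpi=110)
        plt.close(fig)
        return p

    paths.append(_panels(["national", "state"], "trends_national_state.png"))
    if (out / "trend_age.csv").exists():
        paths.append(_panels(["age"], "trends_age.png"))
    if (out / "trend_sex.csv").exists():
        paths.append(_panels(["sex"], "trends_sex.png"))

    # CV comparison with the 25% reference line
    trend = pd.read_csv(_need(out, "trend_detailed.csv"))
    cv = compare_cv(trend, direct)["cells"]
    fig, ax = plt.subplots(figsize=(7, 4))
    years = sorted(cv["year"].unique())
    data_d = [cv.loc[cv["year"] == y, "cv_direct"] for y in years]
    data_m = [cv.loc[cv["year"] == y, "cv_model"] for y in years]
    pos = np.arange(len(years))
    bd = ax.boxplot(data_d, positions=pos - 0.18, widths=0.3, patch_artist=True)
    bm = ax.boxplot(data_m, positions=pos + 0.18, widths=0.3, patch_artist=True)
    for box in bd["boxes"]:
        box.set_facecolor("salmon")
    for box in bm["boxes"]:
        box.set_facecolor("skyblue")
    ax.axhline(25, ls="--", color="k", lw=1)
    ax.set_xticks(pos, [str(y) for y in years])
    ax.set_ylabel("CV (%)")
    ax.set_title("Direct (red) vs model-based (blue) CVs; dashed line = 25%")
    fig.tight_layout()
    p = rep / "cv_comparison.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    # markdown summary with the joinpoint table
    jp_path = out / "joinpoint_results.csv"
    lines = ["# Run report", "", f"Config hash: {_config_hash(cfg)}", ""]
    lines += ["## National trend", ""]
    first, last = trend_nat.iloc[0], trend_nat.iloc[-1]
    lines.append(
        f"Estimated national prevalence: {100 * first['est']:.1f}% in {int(first['year'])} "
        f"to {100 * last['est']:.1f}% in {int(last['year'])}."
    )
    lines += ["", "## Joinpoint results", ""]
    if jp_path.exists():
        jp = pd.read_csv(jp_path)
        if len(jp):
            lines.append(jp.to_markdown(index=False))
        else:
            lines.append("No fits (all series skipped).")
    else:
        lines.append("No fits (joinpoint stage not run).")
    p = rep / "report.md"
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
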