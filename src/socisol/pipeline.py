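"""Full analysis orchestration: metrics, screens, models, reports.

``run_pipeline`` executes the complete analysis on real or simulated
tables: eligibility filtering, per-group-year network construction, the
five isolation metrics with group-year z-scores, derived covariates
(rank, kin, tenure), a pairwise collinearity screen (r² > 0.7 drops a
metric), and for every retained metric three variance-component models —

- Model 1 (all animals): fixed age, sex, rank class; random animal,
  mother, group, year;
- Model 2 (females): fixed age, rank class, number of close adult female
  kin; random animal, mother, group, year;
- Model 3 (males): fixed age, rank class, group tenure; random animal,
  mother, group, year, natal group —

followed by cross-metric association models (each metric regressed on
each other metric, both scaled to unit variance, with age, sex and rank
as fixed effects and year and animal as random intercepts). Reports are
tidy CSV plus one JSON per fit; reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attributes, dataio, networks
from .mixedmodel import MCMCConfig, MixedModelFit, MixedModelSpec, gibbs_fit, interaction_screen
from .networks import METRICS
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "AnalysisConfig",
    "PipelineResult",
    "build_analysis_table",
    "collinearity_screen",
    "model_specs",
    "cross_metric_models",
    "dataset_counts",
    "run_pipeline",
]

log = logging.getLogger("socisol.pipeline")


@dataclass
class AnalysisConfig:
    """What to run and where to write it."""

    outdir: str
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    metrics: list[str] = field(default_factory=lambda: list(METRICS))
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    collinearity_threshold: float = 0.7
    screen_interactions: bool = False
    run_cross_metric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.collinearity_threshold <= 1):
            raise ValueError("collinearity_threshold must be in (0, 1]")
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("give exactly one of simulation= or input_dir=")


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    analysis_table: pd.DataFrame
    metric_table: pd.DataFrame
    r2: pd.DataFrame
    retained_metrics: list[str]
    fits: dict[tuple[str, str], MixedModelFit]  # (model name, metric) -> fit
    cross_metric: pd.DataFrame
    counts: dict[str, int]


def dataset_counts(analysis_table: pd.DataFrame) -> dict[str, int]:
    """Panel size summaries: individual-years, individuals, repeat individuals."""
    per_id = analysis_table.groupby("id")["year"].nunique()
    return {
        "n_individual_years": int(len(analysis_table)),
        "n_individuals": int(analysis_table["id"].nunique()),
        "n_repeat_individuals": int((per_id >= 2).sum()),
    }


def build_analysis_table(
    tables: dataio.DemographyTables,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per eligible individual-year: metrics, z-scores, covariates.

    Returns ``(analysis_table, metric_table)``. Group-years with fewer
    than two eligible individuals are skipped with a log entry; excluded
    individuals (juvenile or partial-year) are logged per group-year.
    """
    group_years = tables.observed_group_years()
    nets = []
    used_group_years = []
    for group, year in group_years:
        mem = tables.membership
        present = set(
            mem[(mem["group"] == group) & (mem["year"] == year)]["id"]
        )
        try:
            ds = dataio.assemble_group_year(tables, group, year)
        except dataio.DegenerateGroupError as exc:
            log.warning("skipping %s %s: %s", group, year, exc)
            continue
        excluded = sorted(present - set(ds.ids))
        if excluded:
            birth = tables.individuals.set_index("id")["birth_year"]
            for i in excluded:
                reason = (
                    "juvenile" if year - int(birth[i]) < dataio.ADULT_AGE
                    else "partial-year"
                )
                log.info("dropped %s from %s %s: %s", i, group, year, reason)
        nets.append(networks.build_rate_matrix(ds))
        used_group_years.append((group, year))

    mt = networks.metric_table(nets)
    pedigree = attributes.Pedigree(tables.pedigree)
    cov = attributes.covariate_table(tables, pedigree, used_group_years)
    df = mt.merge(cov, on=["id", "group", "year"], validate="one_to_one")
    df["animal"] = df["id"]
    n_null_clust = int(df["clustering"].isna().sum())
    if n_null_clust:
        log.info(
            "%d individual-years have null clustering (fewer than 2 partners)"
            " and are dropped from clustering models", n_null_clust,
        )
    n_norank = int(df["rank_class"].isna().sum())
    if n_norank:
        log.info(
            "%d individual-years lack a dominance rank (single same-sex"
            " member) and are dropped from rank-using models", n_norank,
        )
    return df, mt


def collinearity_screen(
    metric_df: pd.DataFrame,
    threshold: float = 0.7,
    metrics: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise r² among z-scored metrics; greedy retention below threshold.

    r² is the squared Pearson correlation over pooled individual-years
    (pairwise-complete). Metrics are visited in canonical order and
    retained unless their r² with an already-retained metric exceeds
    *threshold*.
    """
    metrics = metrics or list(METRICS)
    zcols = [f"z_{m}" for m in metrics]
    r2 = metric_df[zcols].corr() ** 2
    r2.index = metrics
    r2.columns = metrics
    retained: list[str] = []
    for m in metrics:
        if any(r2.loc[m, k] > threshold for k in retained):
            log.warning("metric %s dropped as collinear (r2 > %.2f)", m, threshold)
            continue
        retained.append(m)
    return r2, retained


def model_specs(metric: str) -> dict[str, MixedModelSpec]:
    """The three model specifications for one (z-scored) metric."""
    z = f"z_{metric}"
    return {
        "model1_all": MixedModelSpec(
            response=z,
            fixed_effects=["age", "sex", "rank_class"],
            random_effects=["animal", "mother", "group", "year"],
            subset="all",
        ),
        "model2_females": MixedModelSpec(
            response=z,
            fixed_effects=["age", "rank_class", "n_kin"],
            random_effects=["animal", "mother", "group", "year"],
            subset="females_only",
        ),
        "model3_males": MixedModelSpec(
            response=z,
            fixed_effects=["age", "rank_class", "tenure"],
            random_effects=["animal", "mother", "group", "year", "natal_group"],
            subset="males_only",
        ),
    }


def cross_metric_models(
    df: pd.DataFrame,
    metrics: list[str],
    mcmc: MCMCConfig,
    seed_stream: np.random.Generator,
) -> pd.DataFrame:
    """Association models between every ordered pair of metrics.

    Response and predictor are scaled to unit pooled variance, so the
    predictor coefficient is a standardised regression coefficient; age,
    sex and rank class are covariates and year and animal get random
    intercepts. Pairs with degenerate variance are skipped with a warning.
    """
    rows = []
    work = df.copy()
    for m in metrics:
        s = work[f"z_{m}"].std(ddof=1)
        if not np.isfinite(s) or s == 0:
            log.warning("metric %s has degenerate variance; pairs skipped", m)
            work[f"s_{m}"] = np.nan
        else:
            work[f"s_{m}"] = work[f"z_{m}"] / s
    for resp in metrics:
        for pred in metrics:
            if resp == pred:
                continue
            if work[f"s_{resp}"].isna().all() or work[f"s_{pred}"].isna().all():
                continue
            spec = MixedModelSpec(
                response=f"s_{resp}",
                fixed_effects=[f"s_{pred}", "age", "sex", "rank_class"],
                random_effects=["year", "animal"],
            )
            cfg = MCMCConfig(
                n_iterations=mcmc.n_iterations, burn_in=mcmc.burn_in,
                thin=mcmc.thin, seed=int(seed_stream.integers(2**31)),
                variance_prior=mcmc.variance_prior,
                fixed_prior_variance=mcmc.fixed_prior_variance,
            )
            fit = gibbs_fit(work, spec, cfg)
            fe = fit.fixed_effects.set_index("term").loc[f"s_{pred}"]
            rows.append({
                "response": resp,
                "predictor": pred,
                "coefficient": fe["mean"],
                "lower": fe["lower"],
                "upper": fe["upper"],
                "pmcmc": fe["pmcmc"],
                "n_obs": fit.n_obs,
            })
    return pd.DataFrame(rows)


def _derive_mcmc(base: MCMCConfig, seed: int) -> MCMCConfig:
    return MCMCConfig(
        n_iterations=base.n_iterations, burn_in=base.burn_in, thin=base.thin,
        seed=seed, variance_prior=base.variance_prior,
        fixed_prior_variance=base.fixed_prior_variance,
    )


def run_pipeline(cfg: AnalysisConfig) -> PipelineResult:
    """Execute the whole analysis and write the report bundle.

    Writes into ``cfg.outdir``: metrics.csv, analysis_table.csv,
    collinearity.csv, fits/<model>_<metric>.json, fixed_effects.csv,
    variance_proportions.csv, cross_metric.csv, counts.json and run.log.
    Fully deterministic for a fixed configuration and seed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if cfg.simulation is not None:
            log.info("generating synthetic dataset (seed %d)", cfg.simulation.seed)
            tables = generate_dataset(cfg.simulation).tables
        else:
            log.info("loading tables from %s", cfg.input_dir)
            tables = dataio.load_tables(cfg.input_dir)

        df, mt = build_analysis_table(tables)
        counts = dataset_counts(df)
        log.info(
            "analysis panel: %d individual-years, %d individuals, %d with"
            " repeated years", counts["n_individual_years"],
            counts["n_individuals"], counts["n_repeat_individuals"],
        )

        r2, retained = collinearity_screen(df, cfg.collinearity_threshold, cfg.metrics)

        seed_stream = np.random.default_rng(cfg.seed)
        fits: dict[tuple[str, str], MixedModelFit] = {}
        for metric in retained:
            for name, spec in model_specs(metric).items():
                mc = _derive_mcmc(cfg.mcmc, int(seed_stream.integers(2**31)))
                if cfg.screen_interactions:
                    spec = interaction_screen(df, spec, mc)
                fit = gibbs_fit(df, spec, mc)
                fits[(name, metric)] = fit
                fit.to_json(out / "fits" / f"{name}_{metric}.json")
                log.info(
                    "%s %s: n=%d, repeatability=%.3f", name, metric,
                    fit.n_obs, fit.repeatability,
                )

        cross = pd.DataFrame()
        if cfg.run_cross_metric and len(retained) >= 2:
            cross = cross_metric_models(df, retained, cfg.mcmc, seed_stream)

        # tidy reports
        mt.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
        df.to_csv(out / "analysis_table.csv", index=False, float_format="%.6f")
        r2.round(6).to_csv(out / "collinearity.csv")
        fe_rows, vp_rows = [], []
        for (name, metric), fit in fits.items():
            fe = fit.fixed_effects.assign(model=name, metric=metric)
            fe_rows.append(fe)
            vp = fit.proportions.assign(model=name, metric=metric)
            vp_rows.append(vp)
        if fe_rows:
            pd.concat(fe_rows).round(6).to_csv(out / "fixed_effects.csv", index=False)
            pd.concat(vp_rows).round(6).to_csv(
                out / "variance_proportions.csv", index=False
            )
        if len(cross):
            cross.round(6).to_csv(out / "cross_metric.csv", index=False)
        with open(out / "counts.json", "w") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)

        return PipelineResult(
            analysis_table=df,
            metric_table=mt,
            r2=r2,
            retained_metrics=retained,
            fits=fits,
            cross_metric=cross,
            counts=counts,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
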