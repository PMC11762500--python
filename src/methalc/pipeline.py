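"""End-to-end driver: simulate (or ingest) -> phenotype prep -> EpiScore
design grid -> final full-cohort model -> mixture-prior EWAS -> association
battery, with a machine-readable JSON summary.

Every stage logs one structured line (stage, wall time, parameter digest) and
every numeric result in the summary is traceable to a stage and the seed it
ran under.  Reruns of the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import adjust_battery, battery_table, fit_continuous
from .bayesr import BayesRConfig, call_significant, geweke, gibbs_sample, precorrect, summarize
from .episcore import design_grid, evaluate, impute_missing, preselect_features, project, train_elastic_net
from .io import RunConfig, read_cohort, read_cpg_list, read_matrix, write_cohort, write_matrix
from .phenotype import categorize_drinker, log_units
from .synthgen import (
    EffectArchitecture,
    ReportingModel,
    SyntheticCohort,
    simulate_methylome,
    simulate_phenotype,
    split_cohort,
    to_m_values,
)

logger = logging.getLogger(__name__)


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


class _Stage:
    def __init__(self, name: str, params: dict):
        self.name, self.params = name, params

    def __enter__(self):
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            logger.error("stage=%s failed: %s", self.name, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info(
            "stage=%s wall=%.2fs params=%s", self.name, time.time() - self.t0,
            _digest(self.params),
        )


def _build_cohort(config: RunConfig) -> SyntheticCohort:
    if config.matrix_path and config.cohort_path:
        methyl = read_matrix(config.matrix_path)
        cohort = read_cohort(config.cohort_path)
        return SyntheticCohort(methyl=methyl, cohort=cohort.loc[methyl.index], truth=None)
    arch = EffectArchitecture(**config.arch)
    rep = ReportingModel(**config.reporting)
    methyl = simulate_methylome(
        config.n_samples, config.n_cpgs, config.n_batches, seed=config.seed
    )
    return simulate_phenotype(methyl, arch=arch, report=rep, seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": _digest(asdict(config)),
        "stages": {},
    }

    with _Stage("cohort", {"n": config.n_samples, "p": config.n_cpgs}):
        data = _build_cohort(config)
        write_matrix(data.methyl, out / "methyl.tsv")
        write_cohort(data.cohort, out / "cohort.tsv")
        cats = categorize_drinker(data.cohort["units_last_week"], data.cohort["sex"])
        summary["stages"]["cohort"] = {
            "seed": config.seed,
            "n_samples": int(data.n_samples),
            "n_cpgs": int(data.methyl.shape[1]),
            "drinker_categories": cats.value_counts().to_dict(),
            "mean_units": float(data.cohort["units_last_week"].mean()),
        }

    preselect = None
    if config.preselect_path:
        preselect = read_cpg_list(config.preselect_path)
    elif data.truth is not None and data.truth.causal_cpgs:
        preselect = data.truth.causal_cpgs  # causal-enriched stand-in list

    with _Stage("split", {"fraction": config.train_fraction}):
        train, test = split_cohort(
            data, fractions=(config.train_fraction, 1 - config.train_fraction),
            seed=config.seed,
        )
        summary["stages"]["split"] = {
            "seed": config.seed, "n_train": train.n_samples, "n_test": test.n_samples,
        }

    if config.run_grid:
        with _Stage("design_grid", config.episcore):
            feature_sets = {"all": None}
            if preselect:
                feature_sets["preselected"] = preselect
            grid = design_grid(
                train, test, feature_sets=feature_sets, seed=config.seed,
                **config.episcore,
            )
            grid.to_csv(out / "design_grid.tsv", sep="\t", index=False)
            summary["stages"]["design_grid"] = {
                "seed": config.seed,
                "n_models": int(grid[["feature_set", "training_subset"]].drop_duplicates().shape[0]),
                "best_r_all_subset": float(grid.loc[grid["eval_subset"] == "all", "r"].max()),
            }

    if config.run_final_model:
        with _Stage("final_model", config.episcore):
            X = data.methyl if not preselect else preselect_features(data.methyl, preselect)
            model = train_elastic_net(
                impute_missing(X),
                log_units(data.cohort["units_last_week"].to_numpy()),
                seed=config.seed, **config.episcore,
            )
            score = project(model, test.methyl)
            rep = evaluate(
                score, test.cohort["units_last_week"], test.cohort["age"],
                test.cohort["sex"], subset_label="test",
            )
            pd.DataFrame(
                {"weight": model.weights, "mean": model.feature_means, "sd": model.feature_sds}
            ).to_csv(out / "episcore_weights.tsv", sep="\t", index_label="cpg")
            summary["stages"]["final_model"] = {
                "seed": config.seed, "n_selected_features": model.n_features,
                "test_r": rep.pearson_r, "test_incremental_r2": rep.incremental_r2,
                "test_n": rep.n,
            }

    if config.run_ewas:
        with _Stage("ewas", config.bayesr):
            bcfg = BayesRConfig(seed=config.seed, **config.bayesr)
            X_std, y_resid = precorrect(
                to_m_values(data.methyl),
                data.cohort["units_last_week"],
                data.cohort[["age", "sex", "smoking_score"]],
                batch=data.cohort["batch"],
            )
            chains = gibbs_sample(X_std, y_resid, bcfg)
            post = summarize(chains)
            leads = call_significant(post, bcfg.pip_threshold)
            post.table.to_csv(out / "ewas_summary.tsv", sep="\t", index_label="cpg")
            summary["stages"]["ewas"] = {
                "seed": config.seed,
                "var_explained_mean": post.var_explained_mean,
                "var_explained_sum_sq": post.sum_sq_mean,
                "var_explained_ci": list(post.var_explained_ci),
                "n_lead_cpgs": int(len(leads)),
                "lead_cpgs": list(leads.index),
                "geweke_z_var_explained": geweke(post.var_explained_draws),
            }

    if config.run_assoc:
        with _Stage("assoc", {}):
            results = []
            # synthetic check: does each exposure track the habitual phenotype?
            if data.truth is not None:
                habit = data.truth.habitual_log
                for label, expo in (
                    ("self_report", log_units(data.cohort["units_last_week"].to_numpy())),
                    ("true_score", data.truth.true_score.to_numpy()),
                ):
                    results.append(
                        fit_continuous(
                            habit.to_numpy(), expo, data.cohort["age"], data.cohort["sex"],
                            outcome_label="habitual_log", exposure_label=label,
                        )
                    )
            results = adjust_battery(results)
            tab = battery_table(results)
            tab.to_csv(out / "associations.tsv", sep="\t", index=False)
            summary["stages"]["assoc"] = {
                "seed": config.seed, "n_associations": int(len(tab)),
            }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
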