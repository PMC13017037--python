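"""Configuration-driven orchestration of the full trait-covariation analysis.

One :class:`RunConfig` drives every stage — cohort generation or ingestion,
trait scoring, the chance-performance null, univariate statistics, multiple
imputation, and network estimation with centrality and stability
diagnostics — writing every intermediate artifact plus a consolidated JSON
report into a run directory. A single master seed derives per-stage seeds
deterministically, so re-running an identical config reproduces every
stochastic output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .chance import pvalue_observed, simulate_chance_experiment
from .cohort import CohortConfig, RawCohort, generate_cohort
from .impute import pmm_impute
from .network import (
    CovarianceNetwork,
    centrality,
    correlation_matrix,
    cs_coefficient,
    edge_bootstrap,
)
from .scoring import NETWORK_TRAITS_12, TRAITS, build_trait_table
from .stats import learning_curve_fit, univariate_report

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("cohort", "chance", "imputation", "edge_bootstrap", "cs")


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    ``control=True`` switches to the raw-variable robustness preset: raw
    stress-condition ventilation instead of the percent-increase index, raw
    reversal days instead of the flexibility index, and first-trial-only
    lateralization scores.
    """

    # input source: synthetic config (dict of CohortConfig overrides) or a
    # directory of raw tables written by RawCohort.to_dir
    cohort: dict = field(default_factory=dict)
    raw_dir: Optional[str] = None
    # aggregation switches
    control: bool = False
    node_set: int = 12
    # estimator
    estimator: str = "ebicglasso"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    pooling: str = "fisher-z"
    # stage parameters
    imputation_m: int = 5
    imputation_maxit: int = 50
    imputation_donors: int = 5
    chance_replicates: int = 10_000
    edge_boot: int = 1000
    cs_boot: int = 1000
    cs_metrics: tuple = ("strength", "eigenvector", "expected_influence")
    cs_drop_grid: Optional[list] = None
    r_threshold: float = 0.7
    certainty: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_set not in (12, 14):
            raise ValueError("node_set must be 12 or 14")
        if self.estimator not in ("ebicglasso", "correlation"):
            raise ValueError("estimator must be 'ebicglasso' or 'correlation'")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        idx = _STAGES.index(stage)
        return int((self.seed * 1_000_003 + 7919 * (idx + 1)) % (2**31 - 1))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cs_metrics"] = list(self.cs_metrics)
        return json.dumps(d, indent=1, default=str)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "cs_metrics" in d:
            d["cs_metrics"] = tuple(d["cs_metrics"])
        return cls(**d)


def _node_columns(config: RunConfig) -> list[str]:
    return list(TRAITS) if config.node_set == 14 else list(NETWORK_TRAITS_12)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order and write artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("traitnet")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"version": __version__, "config": json.loads(config.to_json())}
    stage = "setup"
    try:
        # ---- cohort ------------------------------------------------------
        stage = "cohort"
        if config.raw_dir is not None:
            cohort = RawCohort.from_dir(config.raw_dir)
            log.info("loaded raw cohort from %s", config.raw_dir)
        else:
            ccfg = CohortConfig(
                **{"seed": config.stage_seed("cohort"), **config.cohort}
            )
            cohort = generate_cohort(ccfg)
            log.info("generated synthetic cohort: %d subjects, seed %d",
                     ccfg.n_subjects, ccfg.seed)
        cohort.to_dir(out / "cohort")

        # ---- scoring -----------------------------------------------------
        stage = "scoring"
        if config.control:
            table = build_trait_table(
                cohort, lateralization_trials="first", stress="raw",
                flexibility="raw_days",
            )
        else:
            table = build_trait_table(cohort)
        table.to_csv(out / "trait_table.csv")
        (out / "trait_table.json").write_text(json.dumps({
            "aggregation": "first-trial+raw" if config.control else "mean-of-trials",
            "columns": list(table.columns),
        }, indent=1))
        n_missing = int(table.isna().sum().sum())
        report["trait_table"] = {
            "n_subjects": len(table),
            "n_missing_cells": n_missing,
            "missing_fraction": n_missing / table.size,
        }

        # ---- chance null -------------------------------------------------
        stage = "chance"
        max_days = table["spatial_learning"].max()
        n_learn = int(table["spatial_learning"].notna().sum())
        n_days = int(max_days) if np.isfinite(max_days) else 8
        null = simulate_chance_experiment(
            max(n_learn, 1), max(n_days, 2),
            n_replicates=config.chance_replicates,
            seed=config.stage_seed("chance"),
        )
        observed = n_learn  # every scored subject reached criterion by design
        report["chance_null"] = {
            **null.summary(),
            "observed_successes": observed,
            "p_observed": pvalue_observed(null, observed),
        }
        pd.DataFrame({"percentage": null.replicate_percentages}).to_csv(
            out / "chance_null_replicates.csv", index=False
        )

        # ---- univariate stats --------------------------------------------
        stage = "univariate"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats_table = univariate_report(cohort, table)
        stats_table.to_csv(out / "univariate_stats.csv", index=False)
        learn = cohort.maze[cohort.maze.phase == "learning"]
        if len(learn):
            daily = {
                s: g.groupby("day")["correct"].sum().sort_index().to_list()
                for s, g in learn.groupby("subject")
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = learning_curve_fit(daily)
            report["learning_curve"] = {
                "slope": fit.slope, "chi_square": fit.chi_square, "p": fit.p,
                "subject_sd": fit.subject_sd, "separation": fit.separation,
            }

        # ---- imputation ---------------------------------------------------
        stage = "imputation"
        nodes = _node_columns(config)
        node_table = table[nodes]
        if node_table.isna().any().any():
            imputations = pmm_impute(
                node_table,
                m=config.imputation_m,
                maxit=config.imputation_maxit,
                donors=config.imputation_donors,
                seed=config.stage_seed("imputation"),
            )
            for i, t in enumerate(imputations.completed_tables, start=1):
                t.to_csv(out / f"imputed_{i}.csv")
            network_input = correlation_matrix(imputations, pooling=config.pooling)
            pooled_table = imputations.completed_tables[0]
            report["imputation"] = {
                "m": imputations.m, "maxit": imputations.maxit,
                "donors": imputations.donors,
            }
        else:
            network_input = correlation_matrix(node_table)
            pooled_table = node_table
            report["imputation"] = None
        network_input.rho.to_csv(out / "correlation_matrix.csv")
        network_input.pvalues.to_csv(out / "correlation_pvalues.csv")

        # ---- network ------------------------------------------------------
        stage = "network"
        est = CovarianceNetwork(
            estimator=config.estimator, gamma=config.gamma,
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        )
        net = CovarianceNetwork(**est.get_params()).fit(network_input)
        net.weights_frame().to_csv(out / "network_weights.csv")
        cent = centrality(net)
        cent.to_csv(out / "centrality.csv")
        report["network"] = {
            "estimator": config.estimator,
            "lambda": net.lambda_,
            "n_nonzero_edges": int(
                np.sum(np.abs(net.weights_[np.triu_indices(len(nodes), 1)]) > 1e-10)
            ),
        }

        stage = "edge_bootstrap"
        stability = edge_bootstrap(
            pooled_table, estimator=est, n_boot=config.edge_boot,
            seed=config.stage_seed("edge_bootstrap"),
        )
        stability.edges.to_csv(out / "edges.csv", index=False)
        report["edges"] = {
            "n_boot": stability.n_boot,
            "n_significant": int(stability.edges["significant"].sum()),
            "n_degenerate_resamples": stability.n_degenerate,
        }

        stage = "cs"
        cs_rows = []
        for metric in config.cs_metrics:
            res = cs_coefficient(
                pooled_table, metric=metric, estimator=est,
                drop_grid=config.cs_drop_grid,
                n_boot=config.cs_boot, r_threshold=config.r_threshold,
                certainty=config.certainty, seed=config.stage_seed("cs"),
            )
            cs_rows.append({
                "metric": metric,
                "cs_coefficient": res.cs_coefficient,
                "reliable": res.reliable,
            })
        cs_table = pd.DataFrame(cs_rows)
        cs_table.to_csv(out / "cs_coefficients.csv", index=False)
        report["cs"] = cs_rows

        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        log.info("pipeline complete: %s", out)
        return report
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
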