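"""End-to-end orchestration: preprocess -> select -> outlier-filter -> CV.

The default stage order runs the attribute search before K-means outlier
filtering; ``order="cluster-first"`` swaps the two (the two orderings answer
slightly different questions and both are legitimate pipelines, so the choice
is configuration, not code). Every stage records provenance — which columns
were dropped and why, which rows were removed as outliers — so the final
report conserves row and feature accounting and can be reproduced exactly
from its own config echo and seed.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import naive_bayes as nb
from .baselines import BASELINES, BaselineConfig
from .clustering import OutlierRule, column_outlier_indices, fit_kmeans, remove_outliers
from .evaluation import cross_validate, latency
from .preprocess import distance_matrix, fit_normalizer, apply_normalizer, impute_missing
from .search import SearchConfig, SelectionResult, exhaustive_select, mmas_select
from .tabular import DataTable


@dataclass(frozen=True)
class PipelineConfig:
    # stage toggles (ablations)
    impute: bool = True
    normalize: bool = True
    refit_per_fold: bool = False  # leakage-free variant; default normalizes once
    use_mmas: bool = True
    use_clustering: bool = True
    order: str = "select-first"  # or "cluster-first"
    method: str = "mmas"  # mmas | exhaustive | greedy_stepwise | best_first | genetic | pso
    # sub-configs
    search: SearchConfig = field(default_factory=SearchConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    cluster_k: int = 2
    cluster_max_iter: int = 300
    cluster_init: str = "forgy"
    outlier: OutlierRule = field(default_factory=OutlierRule)
    outlier_axis: str = "rows"  # or "columns"
    cv_k: int = 10
    stratified: bool = True
    alpha: float = 1.0
    var_floor: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("select-first", "cluster-first"):
            raise ValueError(f"unknown stage order {self.order!r}")
        if self.outlier_axis not in ("rows", "columns"):
            raise ValueError(f"unknown outlier_axis {self.outlier_axis!r}")
        if self.method not in ("mmas", "exhaustive", "none") and self.method not in BASELINES:
            raise ValueError(f"unknown selection method {self.method!r}")

    def reseeded(self) -> "PipelineConfig":
        """Propagate the global seed into every stage deterministically."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        sub = [int(s & 0x7FFFFFFF) for s in state]
        return replace(
            self,
            search=replace(
                self.search,
                seed=sub[0],
                alpha=self.alpha,
                var_floor=self.var_floor,
            ),
            baseline=replace(self.baseline, seed=sub[1]),
        )

    @property
    def cluster_seed(self) -> int:
        return int(np.random.SeedSequence(self.seed).generate_state(3)[2] & 0x7FFFFFFF)


def config_echo(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def run_selector(table: DataTable, config: PipelineConfig) -> SelectionResult:
    """Dispatch the configured subset-selection method."""
    if config.method == "mmas":
        return mmas_select(table, config.search)
    if config.method == "exhaustive":
        return exhaustive_select(table, config.search)
    return BASELINES[config.method](
        table, config.baseline, search_config=config.search
    )


def run_pipeline(table: DataTable, config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return a self-describing report."""
    config = config.reseeded()
    t_start = time.perf_counter()
    report: dict = {
        "seed": config.seed,
        "config": config_echo(config),
        "n_rows_initial": table.n_rows,
        "n_features_initial": table.n_cols,
        "stages": [],
    }

    if config.impute:
        table = impute_missing(table)
        report["stages"].append({"stage": "impute"})
    if config.normalize and not config.refit_per_fold:
        table = apply_normalizer(table, fit_normalizer(table))
        report["stages"].append({"stage": "normalize", "scope": "full-table"})

    def select_stage(t: DataTable) -> DataTable:
        result = run_selector(t, config)
        report["selection"] = {
            "method": result.method,
            "selected_mask": [bool(b) for b in result.best_subset.mask],
            "selected_features": result.selected_names,
            "best_fitness": result.best_fitness,
            "iterations_run": result.iterations_run,
            "n_evaluations": result.n_evaluations,
            "trajectory": result.trajectory,
        }
        report["stages"].append(
            {
                "stage": "select",
                "method": result.method,
                "features_dropped": [
                    name
                    for name, kept in zip(t.column_names, result.best_subset.mask)
                    if not kept
                ],
                "reason": "below-optimal wrapper fitness",
            }
        )
        return t.select_columns(result.best_subset.mask)

    def cluster_stage(t: DataTable) -> DataTable:
        rows = distance_matrix(t)
        model = fit_kmeans(
            rows,
            k=config.cluster_k,
            seed=config.cluster_seed,
            max_iter=config.cluster_max_iter,
            init=config.cluster_init,
        )
        if config.outlier_axis == "rows":
            filtered, dropped = remove_outliers(t, model, config.outlier, rows=rows)
            report["stages"].append(
                {
                    "stage": "cluster_filter",
                    "axis": "rows",
                    "k": model.k,
                    "inertia": model.inertia,
                    "rows_dropped": [int(i) for i in dropped],
                    "reason": f"distance > cluster mean + {config.outlier.z_cut} SD",
                }
            )
            if filtered.n_rows == 0:
                raise ValueError("outlier filtering removed every row")
            return filtered
        dropped_cols = column_outlier_indices(t, model)
        keep = [i not in dropped_cols for i in range(t.n_cols)]
        report["stages"].append(
            {
                "stage": "cluster_filter",
                "axis": "columns",
                "k": model.k,
                "columns_dropped": [t.column_names[i] for i in dropped_cols],
                "reason": "no correlation with either cluster",
            }
        )
        return t.select_columns(keep) if any(dropped_cols) else t

    stages = []
    if config.order == "select-first":
        if config.use_mmas and config.method != "none":
            stages.append(select_stage)
        if config.use_clustering:
            stages.append(cluster_stage)
    else:
        if config.use_clustering:
            stages.append(cluster_stage)
        if config.use_mmas and config.method != "none":
            stages.append(select_stage)
    for stage in stages:
        table = stage(table)

    cv = cross_validate(
        table,
        k=config.cv_k,
        seed=config.seed,
        nb_config=nb.NBConfig(alpha=config.alpha, var_floor=config.var_floor),
        stratified=config.stratified,
        refit_normalizer=config.normalize and config.refit_per_fold,
    )
    report["n_rows_final"] = table.n_rows
    report["n_features_final"] = table.n_cols
    report["selected_features"] = report.get("selection", {}).get(
        "selected_features", table.column_names
    )
    report["cv"] = {
        "k": config.cv_k,
        "fold_accuracies": cv.fold_accuracies,
        "mean_accuracy": cv.mean_accuracy,
        "pooled_confusion": {
            "tp": cv.pooled_confusion.tp,
            "tn": cv.pooled_confusion.tn,
            "fp": cv.pooled_confusion.fp,
            "fn": cv.pooled_confusion.fn,
        },
    }
    report["metrics"] = cv.metrics
    report["latency_s"] = latency(cv)
    report["wall_time_s"] = time.perf_counter() - t_start
    return report


COMPARE_METHODS = ["mmas", "greedy_stepwise", "best_first", "genetic", "pso"]


def run_compare(
    table: DataTable, methods: list[str] | None = None, config: PipelineConfig | None = None
) -> list[dict]:
    """Run the pipeline once per selection method; one summary row each.

    Rows carry the comparison-table shape: instance count, initial and
    reduced attribute counts, the five metrics, and latency.
    """
    methods = methods or list(COMPARE_METHODS)
    config = config or PipelineConfig()
    if not methods:
        raise ValueError("need at least one method to compare")
    rows = []
    for method in methods:
        report = run_pipeline(table, replace(config, method=method))
        rows.append(
            {
                "method": method,
                "n_instances": report["n_rows_initial"],
                "initial_attributes": report["n_features_initial"],
                "reduced_attributes": len(report["selected_features"]),
                "fitness": report.get("selection", {}).get("best_fitness"),
                "accuracy": report["metrics"]["accuracy"],
                "precision": report["metrics"]["precision"],
                "recall": report["metrics"]["recall"],
                "f_score": report["metrics"]["f_score"],
                "mcc": report["metrics"]["mcc"],
                "latency_s": report["latency_s"],
                "n_selected": len(report["selected_features"]),
            }
        )
    return rows
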