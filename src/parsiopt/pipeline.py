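"""Study orchestration: replicated optimizer runs and cross-method statistics.

Runs each stochastic strategy (random search, genetic algorithm, TPE) a
number of times with derived seeds against one fitness callable, collects
the best NER_T per replica, and compares methods with two-sided Welch
t-tests at the 95% level.  Grid search is optional and refused above a
configurable space-size cap, since it evaluates every grid point.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import (
    GlobalMetrics,
    confusion,
    cv_fitness,
    global_metrics,
    optimize_thresholds,
)
from .multitask_net import TaskLabelMatrix, TrainingConfig, predict, train
from .optimizers import (
    RunHistory,
    ga_optimize,
    grid_search,
    random_search,
    tpe_optimize,
)
from .search_space import ArchitectureConfig, HyperparameterSpace
from .synthetic_data import SurrogateLandscape, surrogate_fitness

__all__ = [
    "SurrogateFitness",
    "CrossValidationFitness",
    "ComparisonReport",
    "run_study",
    "welch_ttest",
    "external_test_eval",
]


class SurrogateFitness:
    """Callable fitness backed by the additive surrogate landscape."""

    def __init__(self, landscape: SurrogateLandscape, seed: int = 0):
        self.landscape = landscape
        self.rng = np.random.default_rng(seed)

    def __call__(self, config: ArchitectureConfig) -> float:
        return surrogate_fitness(self.landscape, config, self.rng)


class CrossValidationFitness:
    """Callable fitness = k-fold cross-validated NER_T of a trained network.

    Keeps the full GlobalMetrics of every evaluated configuration in
    ``metrics_log`` so SN_T-vs-SP_T scatter data can be reported.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: TaskLabelMatrix,
        k: int = 3,
        seed: int = 0,
    ):
        self.features = features
        self.labels = labels
        self.k = k
        self.seed = seed
        self.metrics_log: list[tuple[ArchitectureConfig, GlobalMetrics]] = []

    def __call__(self, config: ArchitectureConfig) -> float:
        m = cv_fitness(
            self.features, self.labels, config, k=self.k, seed=self.seed
        )
        self.metrics_log.append((config, m))
        return m.ner


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test.

    Degenerate case: both samples constant with equal means -> (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class ComparisonReport:
    """Per-method summary over replicas plus pairwise Welch t-tests."""

    summary: pd.DataFrame  # method, mean_best, ci_half, n_replicas, seconds
    pairwise: pd.DataFrame  # method_a, method_b, statistic, p_value
    best_per_replica: dict[str, list[float]]
    top10: pd.DataFrame  # per method: top-10 NER_T (final GA population)
    scatter: pd.DataFrame  # SN_T vs SP_T when the fitness exposes metrics
    histories: dict[str, list[RunHistory]]

    def to_json(self, path: str) -> None:
        payload = {
            "summary": self.summary.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "best_per_replica": self.best_per_replica,
            "top10": self.top10.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _top10(history: RunHistory) -> list[float]:
    """Top-10 NER_T of one run: the final population for the GA, the ten
    best trials for the other strategies."""
    final = [r.fitness for r in history.records if r.in_final_population]
    if final:
        return sorted(final, reverse=True)[:10]
    return sorted((r.fitness for r in history.records), reverse=True)[:10]


def run_study(
    fitness_factory: Callable[[int], Callable[[ArchitectureConfig], float]],
    space: HyperparameterSpace,
    methods: tuple[str, ...] = ("rs", "ga", "tpe"),
    replicas: int = 10,
    budget: int = 100,
    seed: int = 0,
    max_grid: int = 10_000,
) -> ComparisonReport:
    """Run each method ``replicas`` times and compare best-per-replica NER_T.

    ``fitness_factory(seed)`` must return a fresh fitness callable; replica
    seeds are derived as ``seed + replica_index``.  Grid search runs once
    (it is deterministic) and is refused when the space exceeds
    ``max_grid`` points.
    """
    unknown = set(methods) - {"gs", "rs", "ga", "tpe"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if "gs" in methods and space.cardinality > max_grid:
        raise ValueError(
            f"grid search refused: space has {space.cardinality} points "
            f"(cap {max_grid}); raise max_grid to override"
        )

    histories: dict[str, list[RunHistory]] = {m: [] for m in methods}
    best: dict[str, list[float]] = {m: [] for m in methods}
    seconds: dict[str, float] = {}
    top10_rows = []
    scatter_rows = []

    for method in methods:
        t0 = time.perf_counter()
        n_rep = 1 if method == "gs" else replicas
        for rep in range(n_rep):
            rep_seed = seed + rep
            fitness = fitness_factory(rep_seed)
            if method == "gs":
                h = grid_search(space, fitness, replicate=rep)
            elif method == "rs":
                h = random_search(
                    space, fitness, n=budget, seed=rep_seed, replicate=rep
                )
            elif method == "ga":
                h = ga_optimize(
                    space, fitness, seed=rep_seed, budget=budget, replicate=rep
                )
            else:
                h = tpe_optimize(
                    space, fitness, seed=rep_seed, n_trials=budget,
                    replicate=rep,
                )
            histories[method].append(h)
            best[method].append(h.best.fitness)
            for rank, v in enumerate(_top10(h), start=1):
                top10_rows.append(
                    {"method": method, "replicate": rep, "rank": rank,
                     "NER_T": v}
                )
            log = getattr(fitness, "metrics_log", None)
            if log:
                for cfg, m in log:
                    scatter_rows.append(
                        {"method": method, "replicate": rep,
                         "SN_T": m.sn, "SP_T": m.sp, "NER_T": m.ner}
                    )
        seconds[method] = time.perf_counter() - t0

    rows = []
    for method in methods:
        vals = np.asarray(best[method], dtype=float)
        if vals.size > 1 and vals.var(ddof=1) > 0:
            half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(
                vals.size
            )
        else:
            half = 0.0
        rows.append(
            {"method": method, "mean_best_NER_T": float(vals.mean()),
             "ci_half_width": float(half), "n_replicas": int(vals.size),
             "seconds": seconds[method]}
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    stoch = [m for m in methods if m != "gs"]
    for i, ma in enumerate(stoch):
        for mb in stoch[i + 1:]:
            if len(best[ma]) >= 2 and len(best[mb]) >= 2:
                t, p = welch_ttest(best[ma], best[mb])
                pair_rows.append(
                    {"method_a": ma, "method_b": mb,
                     "statistic": t, "p_value": p}
                )
    pairwise = pd.DataFrame(pair_rows)

    top10 = pd.DataFrame(top10_rows)
    if not top10.empty:
        top10 = top10.sort_values(
            ["method", "replicate", "rank"]
        ).reset_index(drop=True)
    scatter = pd.DataFrame(scatter_rows)
    return ComparisonReport(summary, pairwise, best, top10, scatter, histories)


def external_test_eval(
    train_features: np.ndarray,
    train_labels: TaskLabelMatrix,
    test_features: np.ndarray,
    test_labels: TaskLabelMatrix,
    configs: list[ArchitectureConfig],
    seed: int = 0,
    train_indices: np.ndarray | None = None,
    test_indices: np.ndarray | None = None,
) -> list[GlobalMetrics]:
    """Retrain each architecture on the full training set and score it on
    the held-out external test set (thresholds fitted on training scores).

    If the original index vectors are supplied they are checked for
    overlap.
    """
    if train_indices is not None and test_indices is not None:
        if np.intersect1d(train_indices, test_indices).size:
            raise ValueError("train and test indices overlap")
    out = []
    for i, arch in enumerate(configs):
        cfg = TrainingConfig.from_architecture(arch, seed=seed + i)
        weights = train(train_features, train_labels, arch, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = optimize_thresholds(
                train_labels, predict(train_features, weights)
            )
        probs = predict(test_features, weights)
        out.append(global_metrics(confusion(test_labels, probs, thr)))
    return out
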