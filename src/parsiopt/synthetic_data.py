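"""Synthetic multitask fingerprint datasets and a surrogate fitness landscape.

The generator emulates the statistical shape of public multitask QSAR
collections (a nuclear-receptor panel with 30 tasks, a 12-task toxicity
panel, and a 2-task clinical-toxicity set): sparse binary fingerprint-like
features, per-task class imbalance up to 94%/7% actives, large fractions of
missing annotations, and correlated tasks driven by a shared latent factor.
Labels follow a logistic model over a sparse random projection of the
features, so the tasks are learnable by a network and correlated the way
multitask learning assumes.

The surrogate landscape is a cheap additive stand-in for the 3-fold
cross-validated NER_T of a trained network: each hyperparameter level
contributes a fixed utility, plus Gaussian noise.  It lets the search
strategies be exercised end to end in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .multitask_net import TaskLabelMatrix, activate
from .search_space import ArchitectureConfig, HyperparameterSpace

__all__ = [
    "DatasetSpec",
    "SurrogateLandscape",
    "generate",
    "preset",
    "planted_landscape",
    "strong_landscape",
    "surrogate_fitness",
]

N_SIGNAL_FEATURES = 25  # active features per task in the label model


@dataclass
class DatasetSpec:
    """Parameters of one synthetic multitask dataset."""

    n_samples: int = 2000
    n_features: int = 1024
    n_tasks: int = 2
    prevalence: tuple[float, ...] = (0.5, 0.5)
    missing_fraction: tuple[float, ...] = (0.0, 0.0)
    task_correlation: float = 0.5
    feature_density: float = 0.05
    signal_scale: float = 4.0
    signal_kind: str = "weighted"
    seed: int = 0

    def __post_init__(self) -> None:
        self.prevalence = tuple(float(p) for p in self.prevalence)
        self.missing_fraction = tuple(float(m) for m in self.missing_fraction)
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        if len(self.prevalence) != self.n_tasks:
            raise ValueError("one prevalence per task required")
        if len(self.missing_fraction) != self.n_tasks:
            raise ValueError("one missing fraction per task required")
        for p in self.prevalence:
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"prevalence {p} infeasible: must lie strictly in (0, 1)"
                )
        for m in self.missing_fraction:
            if not 0.0 <= m < 1.0:
                raise ValueError("missing fractions must lie in [0, 1)")
        if not 0.0 <= self.task_correlation <= 1.0:
            raise ValueError("task_correlation must lie in [0, 1]")
        if self.signal_kind not in ("weighted", "count"):
            raise ValueError("signal_kind must be 'weighted' or 'count'")

    def to_yaml(self, path: str) -> None:
        d = self.__dict__.copy()
        d["prevalence"] = list(self.prevalence)
        d["missing_fraction"] = list(self.missing_fraction)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "DatasetSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["prevalence"] = tuple(d["prevalence"])
        d["missing_fraction"] = tuple(d["missing_fraction"])
        return cls(**d)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _bisect_intercept(scores: np.ndarray, target: float) -> float:
    """Intercept b such that mean(sigmoid(scores + b)) == target."""
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if float(activate("sigmoid", scores + mid).mean()) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate(spec: DatasetSpec) -> tuple[np.ndarray, TaskLabelMatrix]:
    """Generate (features, labels) under the spec; bit-reproducible per seed.

    Features are iid Bernoulli bits at the requested density.  Each task's
    latent score mixes a shared component (weight sqrt(rho)) with a
    task-specific component (weight sqrt(1-rho)), both linear in a sparse
    random projection of the features; a per-task intercept is tuned by
    bisection so the expected prevalence matches the spec.  Missing cells
    are masked independently (MCAR), then repaired so every sample keeps at
    least one annotation.

    ``signal_kind="weighted"`` (default) draws standard-normal projection
    weights — realistic graded structure-activity signal, only partially
    learnable at small n.  ``signal_kind="count"`` uses unit weights, so the
    latent score is the number of active signal bits (a structural-alert
    rule with feature-space margin 1); combined with
    ``signal_scale=np.inf`` this yields a cleanly learnable, deterministic
    labelling, at the price of the realised prevalence snapping to the
    nearest count-atom boundary.
    """
    rng = np.random.default_rng(spec.seed)
    X = (rng.random((spec.n_samples, spec.n_features)) < spec.feature_density)
    X = X.astype(np.int8)
    Xf = X.astype(float)

    def latent(rg: np.random.Generator) -> np.ndarray:
        cols = rg.choice(spec.n_features, N_SIGNAL_FEATURES, replace=False)
        if spec.signal_kind == "count":
            w = np.ones(N_SIGNAL_FEATURES)
        else:
            w = rg.normal(size=N_SIGNAL_FEATURES)
        return _standardize(Xf[:, cols] @ w)

    z_shared = latent(rng)
    rho = spec.task_correlation
    labels = np.full((spec.n_samples, spec.n_tasks), np.nan)
    for t in range(spec.n_tasks):
        score = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * latent(rng)
        prev = spec.prevalence[t]
        if np.isinf(spec.signal_scale):
            # noise-free labels: threshold at the prevalence quantile
            cut = np.quantile(score, 1.0 - prev)
            y = (score > cut).astype(float)
        else:
            logits = spec.signal_scale * score
            logits += _bisect_intercept(logits, prev)
            y = (rng.random(spec.n_samples) < activate("sigmoid", logits))
            y = y.astype(float)
        labels[:, t] = y

    observed = np.ones_like(labels, dtype=bool)
    for t in range(spec.n_tasks):
        observed[:, t] = rng.random(spec.n_samples) >= spec.missing_fraction[t]
    # repair: every sample keeps >= 1 annotation
    empty = ~observed.any(axis=1)
    if empty.any():
        keep_task = rng.integers(0, spec.n_tasks, size=int(empty.sum()))
        observed[np.where(empty)[0], keep_task] = True
    labels[~observed] = np.nan
    return X, TaskLabelMatrix(labels)


def preset(name: str, full_scale: bool = False, seed: int = 0) -> DatasetSpec:
    """Named dataset specs mirroring the three public benchmarks.

    ``nura``: 30 tasks, heavy missingness; ``tox21``: 12 imbalanced toxicity
    tasks; ``clintox``: 2 fully annotated tasks with opposed prevalences
    (94.1% vs 7.1% actives).  Sample sizes default to a reduced scale
    (n=2000, except clintox which is small enough to keep whole);
    ``full_scale=True`` selects the full benchmark sizes.
    """
    if name == "nura":
        n = 14963 if full_scale else 2000
        return DatasetSpec(
            n_samples=n,
            n_tasks=30,
            prevalence=tuple([0.25] * 30),
            missing_fraction=tuple([0.5] * 30),
            task_correlation=0.5,
            seed=seed,
        )
    if name == "tox21":
        n = 7586 if full_scale else 2000
        return DatasetSpec(
            n_samples=n,
            n_tasks=12,
            prevalence=tuple([0.08] * 12),
            missing_fraction=tuple([0.2] * 12),
            task_correlation=0.5,
            seed=seed,
        )
    if name == "clintox":
        return DatasetSpec(
            n_samples=1472,
            n_tasks=2,
            prevalence=(0.941, 0.071),
            missing_fraction=(0.0, 0.0),
            task_correlation=0.3,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# surrogate fitness landscape


@dataclass
class SurrogateLandscape:
    """Additive per-level utilities + baseline + Gaussian noise, in NER_T
    units (clipped to [0, 100])."""

    utilities: dict[str, dict[Any, float]]
    baseline: float = 55.0
    noise_std: float = 2.0

    def mean_response(self, config: ArchitectureConfig) -> float:
        total = self.baseline
        for factor, table in self.utilities.items():
            total += table.get(config[factor], 0.0)
        return float(np.clip(total, 0.0, 100.0))

    def best_config(self, space: HyperparameterSpace) -> ArchitectureConfig:
        """Argmax of the noise-free response, factor by factor (valid
        because the landscape is additive)."""
        best = {}
        for f in space.factors:
            table = self.utilities.get(f.name, {})
            best[f.name] = max(f.levels, key=lambda v: table.get(v, 0.0))
        return ArchitectureConfig.from_mapping(best)


def planted_landscape(noise_std: float = 2.0) -> SurrogateLandscape:
    """Default planted landscape over the full tuning space.

    Encodes the effect structure the study's effect analysis identifies:
    high learning rate good, many epochs good, L2 regularisation good and
    L1 clearly bad, few third-layer neurons good; the remaining factors are
    flat.  The noise-free optimum is at learning_rate=1e-2, epochs=500,
    penalty=L2, neurons_layer3=0, reaching 86 NER_T units before clipping.
    """
    utilities = {
        "learning_rate": {1e-2: 10.0, 1e-3: 6.0, 1e-4: 2.0, 1e-5: 0.0},
        "epochs": {5: 0.0, 50: 3.0, 200: 6.0, 500: 9.0},
        "penalty": {"none": 4.0, "L1": -8.0, "L2": 6.0},
        "neurons_layer3": {0: 6.0, 100: 3.0, 500: 1.0, 1000: 0.0},
    }
    return SurrogateLandscape(utilities, baseline=55.0, noise_std=noise_std)


def strong_landscape(noise_std: float = 1.0) -> SurrogateLandscape:
    """Landscape with one strongly superior level per factor.

    Every factor carries a +5 utility on a single best level (the factors
    with known effect directions keep them: learning_rate 1e-2, epochs
    500, penalty L2, neurons_layer3 0; the rest are fixed arbitrarily) so
    the optimum is a unique point at 85 that uniform sampling is unlikely
    to hit in 100 draws.  This is the reference terrain for comparing the
    search strategies: informed methods can identify the superior level of
    each factor from few observations, while random search's best-of-100
    typically misses several factors.
    """
    best_levels = {
        "learning_rate": 1e-2,
        "epochs": 500,
        "penalty": "L2",
        "neurons_layer3": 0,
        "neurons_layer1": 1000,
        "neurons_layer2": 100,
        "dropout": 0.1,
        "activation": "relu",
        "optimizer": "adam",
    }
    utilities = {f: {lvl: 5.0} for f, lvl in best_levels.items()}
    return SurrogateLandscape(utilities, baseline=40.0, noise_std=noise_std)


def surrogate_fitness(
    landscape: SurrogateLandscape,
    config: ArchitectureConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One noisy observation of the landscape at ``config``."""
    value = landscape.mean_response(config)
    if landscape.noise_std > 0 and rng is not None:
        value += float(rng.normal(scale=landscape.noise_std))
    return float(np.clip(value, 0.0, 100.0))


# ---------------------------------------------------------------------------
# plain-text persistence


def save_dataset(
    prefix: str, features: np.ndarray, labels: TaskLabelMatrix
) -> None:
    """Write ``<prefix>_features.csv`` and ``<prefix>_labels.csv`` (missing
    labels as empty cells)."""
    pd.DataFrame(features).to_csv(f"{prefix}_features.csv", index=False)
    cols = [f"task_{t}" for t in range(labels.n_tasks)]
    pd.DataFrame(labels.values, columns=cols).to_csv(
        f"{prefix}_labels.csv", index=False
    )


def load_dataset(prefix: str) -> tuple[np.ndarray, TaskLabelMatrix]:
    X = pd.read_csv(f"{prefix}_features.csv").to_numpy(dtype=np.int8)
    y = pd.read_csv(f"{prefix}_labels.csv").to_numpy(dtype=float)
    return X, TaskLabelMatrix(y)
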