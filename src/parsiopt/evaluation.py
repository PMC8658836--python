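"""Pooled multitask classification metrics and cross-validated fitness.

The score of an architecture is the overall non-error rate NER_T: confusion
counts are pooled over all tasks (sums of TP, TN, FP, FN across tasks, not
per-task averages), the pooled sensitivity SN_T and specificity SP_T are
expressed as percentages, and NER_T is their mean.  A compound is called
active when its output probability strictly exceeds the per-task threshold;
a probability equal to the threshold means inactive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .multitask_net import TaskLabelMatrix, TrainingConfig, predict, train
from .search_space import ArchitectureConfig

__all__ = [
    "ConfusionByTask",
    "GlobalMetrics",
    "confusion",
    "global_metrics",
    "optimize_thresholds",
    "stratified_split",
    "stratified_kfold",
    "cv_fitness",
]


@dataclass(frozen=True)
class ConfusionByTask:
    """Per-task confusion counts; arrays of length T."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=int)
            )

    @property
    def n_tasks(self) -> int:
        return self.tp.shape[0]

    def __add__(self, other: "ConfusionByTask") -> "ConfusionByTask":
        return ConfusionByTask(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class GlobalMetrics:
    """Pooled sensitivity, specificity and non-error rate, in percent."""

    sn: float
    sp: float

    @property
    def ner(self) -> float:
        return (self.sn + self.sp) / 2.0

    def as_dict(self) -> dict[str, float]:
        return {"SN_T": self.sn, "SP_T": self.sp, "NER_T": self.ner}


def confusion(
    labels: TaskLabelMatrix,
    probabilities: np.ndarray,
    thresholds: np.ndarray | float,
) -> ConfusionByTask:
    """Per-task confusion counts over the observed cells only.

    Predicted active iff probability > threshold (strict); a score exactly
    at the threshold is predicted inactive.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != labels.values.shape:
        raise ValueError("probabilities and labels must have the same shape")
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float), (labels.n_tasks,))
    pred_active = p > thr[None, :]
    mask = labels.mask
    y = labels.values
    actual_active = mask & (y == 1)
    actual_inactive = mask & (y == 0)
    tp = (actual_active & pred_active).sum(axis=0)
    fn = (actual_active & ~pred_active).sum(axis=0)
    fp = (actual_inactive & pred_active).sum(axis=0)
    tn = (actual_inactive & ~pred_active).sum(axis=0)
    return ConfusionByTask(tp, tn, fp, fn)


def global_metrics(conf: ConfusionByTask) -> GlobalMetrics:
    """Pooled SN_T = 100 * sum TP / (sum TP + sum FN) and the analogous
    SP_T over inactives; NER_T is their mean."""
    tp, fn = int(conf.tp.sum()), int(conf.fn.sum())
    tn, fp = int(conf.tn.sum()), int(conf.fp.sum())
    if tp + fn == 0:
        raise ValueError("no observed actives: pooled sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no observed inactives: pooled specificity undefined")
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    return GlobalMetrics(sn, sp)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.unique(np.concatenate(([0.0], mids, [1.0])))


def optimize_thresholds(
    labels: TaskLabelMatrix, probabilities: np.ndarray
) -> np.ndarray:
    """Per-task assignment thresholds from the ROC of each task's scores.

    For every task, all midpoints between consecutive distinct scores (plus
    0 and 1) are scanned and the threshold maximising the per-task balanced
    accuracy (sensitivity+specificity)/2 is kept; ties go to the smallest
    threshold.  A task observed with a single class gets threshold 0.5 and
    a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    thr = np.full(labels.n_tasks, 0.5)
    for t in range(labels.n_tasks):
        mask = labels.mask[:, t]
        y = labels.values[mask, t]
        s = p[mask, t]
        n_act = int((y == 1).sum())
        n_inact = int((y == 0).sum())
        if n_act == 0 or n_inact == 0:
            warnings.warn(
                f"task {t}: single-class labels, using threshold 0.5",
                stacklevel=2,
            )
            continue
        best_thr, best_ba = 0.5, -np.inf
        for c in _candidate_thresholds(s):
            sens = ((y == 1) & (s > c)).sum() / n_act
            spec = ((y == 0) & (s <= c)).sum() / n_inact
            ba = (sens + spec) / 2.0
            if ba > best_ba + 1e-12:
                best_ba, best_thr = ba, c
        thr[t] = best_thr
    return thr


# ---------------------------------------------------------------------------
# stratified splitting


def stratified_kfold(
    labels: TaskLabelMatrix, k: int, seed: int | np.random.Generator
) -> list[np.ndarray]:
    """Greedy iterative stratification of a multilabel set into k folds.

    Samples are assigned one at a time, ordered by the scarcity of the
    rarest (task, class) annotation they carry, to the fold with the
    largest remaining need for that annotation.  This keeps per-task
    active/inactive proportions close to the full-set proportions in every
    fold, as closely as integer counts allow.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return _iterative_stratification(labels, np.full(k, 1.0 / k), seed)


def stratified_split(
    labels: TaskLabelMatrix,
    test_fraction: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test partition preserving per-task class balance."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = _iterative_stratification(
        labels, np.array([1.0 - test_fraction, test_fraction]), seed
    )
    return groups[0], groups[1]


def _iterative_stratification(
    labels: TaskLabelMatrix,
    proportions: np.ndarray,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n, T = labels.values.shape
    k = proportions.shape[0]
    mask = labels.mask
    y = labels.values

    # one-hot annotation matrix over 2T (class, task) labels
    has = np.zeros((n, 2 * T), dtype=bool)
    for t in range(T):
        has[:, 2 * t] = mask[:, t] & (y[:, t] == 0)
        has[:, 2 * t + 1] = mask[:, t] & (y[:, t] == 1)

    desired = proportions[:, None] * has.sum(axis=0)[None, :]  # k x 2T
    desired_total = proportions * n
    unassigned = np.ones(n, dtype=bool)
    assignment = np.empty(n, dtype=int)

    while unassigned.any():
        remaining = has[unassigned].sum(axis=0)
        remaining = np.where(remaining > 0, remaining, np.iinfo(np.int64).max)
        if remaining.min() == np.iinfo(np.int64).max:
            # only annotation-free samples left: balance group sizes
            for i in np.where(unassigned)[0]:
                g = int(np.argmax(desired_total + 1e-9 * rng.random(k)))
                assignment[i] = g
                desired_total[g] -= 1
                unassigned[i] = False
            break
        lab = int(np.argmin(remaining))  # scarcest remaining annotation
        idx = np.where(unassigned & has[:, lab])[0]
        for i in rng.permutation(idx):
            # group with the greatest need for this annotation; ties by
            # overall remaining capacity, then at random
            key = (
                desired[:, lab]
                + 1e-6 * desired_total
                + 1e-12 * rng.random(k)
            )
            g = int(np.argmax(key))
            assignment[i] = g
            desired[g, has[i]] -= 1
            desired_total[g] -= 1
            unassigned[i] = False
    return [np.sort(np.where(assignment == g)[0]) for g in range(k)]


# ---------------------------------------------------------------------------
# cross-validated fitness


def cv_fitness(
    features: np.ndarray,
    labels: TaskLabelMatrix,
    arch: ArchitectureConfig,
    k: int = 3,
    seed: int = 0,
    batch_size: int = 128,
    penalty_weight: float = 1e-4,
) -> "GlobalMetrics":
    """k-fold cross-validated pooled metrics of one architecture.

    For each fold a fresh network is trained on the remaining folds,
    per-task thresholds are optimised on the held-out fold's scores, and
    the held-out confusion counts are pooled across folds before computing
    SN_T/SP_T/NER_T.  NER_T of the returned metrics is the fitness scalar.
    """
    X = np.asarray(features, dtype=float)
    folds = stratified_kfold(labels, k, np.random.default_rng(seed))
    total: ConfusionByTask | None = None
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.sort(
            np.concatenate([f for j, f in enumerate(folds) if j != fold_id])
        )
        cfg = TrainingConfig.from_architecture(
            arch, seed=seed + 1000 * (fold_id + 1)
        )
        cfg.batch_size = batch_size
        cfg.penalty_weight = penalty_weight
        weights = train(X[train_idx], labels.subset(train_idx), arch, cfg)
        probs = predict(X[test_idx], weights)
        fold_labels = labels.subset(test_idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = optimize_thresholds(fold_labels, probs)
        conf = confusion(fold_labels, probs, thr)
        total = conf if total is None else total + conf
    assert total is not None
    return global_metrics(total)
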