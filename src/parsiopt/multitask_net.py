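"""Self-contained multitask fully connected network.

One network with up to three shared hidden layers and one sigmoid output
node per task, trained jointly with a binary cross-entropy loss that skips
missing labels, so each compound contributes supervision only for the tasks
it is annotated for.  Forward pass, backpropagation and the mini-batch
update rules (SGD, Adam, RMSprop, Adagrad) are implemented directly on
numpy arrays; no deep-learning framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .search_space import ArchitectureConfig

__all__ = [
    "TaskLabelMatrix",
    "TrainingConfig",
    "NetworkWeights",
    "activate",
    "activate_grad",
    "masked_bce_loss",
    "init_weights",
    "train",
    "predict",
]

EPS = 1e-7  # probability clipping before the log
N_FEATURES_DEFAULT = 1024


# ---------------------------------------------------------------------------
# labels


@dataclass
class TaskLabelMatrix:
    """Samples x tasks label matrix with values in {1 active, 0 inactive,
    NaN missing}.  Every sample must carry at least one annotation."""

    values: np.ndarray
    allow_empty_rows: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError("labels must be a 2-D samples x tasks matrix")
        finite = np.isfinite(v)
        if not np.all((v[finite] == 0) | (v[finite] == 1)):
            raise ValueError("non-missing labels must be 0 or 1")
        if (
            not self.allow_empty_rows
            and v.shape[0] > 0
            and not finite.any(axis=1).all()
        ):
            raise ValueError("every sample needs at least one non-missing label")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix: True where a label is observed."""
        return np.isfinite(self.values)

    def subset(self, rows: np.ndarray) -> "TaskLabelMatrix":
        return TaskLabelMatrix(self.values[rows], allow_empty_rows=True)


# ---------------------------------------------------------------------------
# activations


def activate(kind: str, z: np.ndarray) -> np.ndarray:
    """Elementwise activation: sigmoid 1/(1+e^-z), relu max(0,z),
    tanh, or elu (e^z - 1 for z<0, z otherwise)."""
    z = np.asarray(z, dtype=float)
    if kind == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if kind == "relu":
        return np.maximum(0.0, z)
    if kind == "tanh":
        return np.tanh(z)
    if kind == "elu":
        return np.where(z < 0, np.expm1(z), z)
    raise ValueError(f"unknown activation {kind!r}")


def activate_grad(kind: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Derivative of the activation wrt its input, given z and a=f(z)."""
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "tanh":
        return 1.0 - a * a
    if kind == "elu":
        return np.where(z < 0, a + 1.0, 1.0)
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# weights


@dataclass
class NetworkWeights:
    """Per-layer weight matrices W (in x out) and bias vectors b."""

    W: list[np.ndarray]
    b: list[np.ndarray]
    hidden_activation: str = "relu"

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            [w.copy() for w in self.W],
            [bb.copy() for bb in self.b],
            self.hidden_activation,
        )

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def l1(self) -> float:
        return float(sum(np.abs(w).sum() for w in self.W))

    def l2(self) -> float:
        return float(sum((w * w).sum() for w in self.W))


def init_weights(
    n_inputs: int,
    hidden: tuple[int, ...],
    n_tasks: int,
    rng: np.random.Generator,
    hidden_activation: str = "relu",
    std: float = 0.05,
    trunc: float = 2.0,
) -> NetworkWeights:
    """Truncated-normal initialisation (mean 0, std 0.05, cut at 2 std);
    biases start at zero."""
    sizes = [n_inputs, *hidden, n_tasks]
    W, b = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = truncnorm.rvs(
            -trunc, trunc, scale=std, size=(fan_in, fan_out), random_state=rng
        )
        W.append(np.asarray(w))
        b.append(np.zeros(fan_out))
    return NetworkWeights(W, b, hidden_activation)


# ---------------------------------------------------------------------------
# loss


def _penalty_value(weights: NetworkWeights, penalty: str, penalty_weight: float) -> float:
    if penalty == "none" or penalty_weight == 0.0:
        return 0.0
    if penalty == "L1":
        return penalty_weight * weights.l1()
    if penalty == "L2":
        return penalty_weight * weights.l2()
    raise ValueError(f"unknown penalty {penalty!r}")


def masked_bce_loss(
    predictions: np.ndarray,
    labels: TaskLabelMatrix,
    weights: NetworkWeights | None = None,
    penalty: str = "none",
    penalty_weight: float = 0.0,
) -> float:
    """Binary cross-entropy averaged over the observed (sample, task) cells
    only, plus an optional L1/L2 penalty on the weight matrices (biases are
    never penalised)."""
    p = np.clip(np.asarray(predictions, dtype=float), EPS, 1.0 - EPS)
    mask = labels.mask
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed labels: loss undefined")
    y = np.where(mask, labels.values, 0.0)
    cell = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    loss = float(cell[mask].sum() / n_obs)
    if penalty != "none" and weights is None:
        raise ValueError("weights required to compute a penalty")
    if weights is not None:
        loss += _penalty_value(weights, penalty, penalty_weight)
    return loss


# ---------------------------------------------------------------------------
# forward / backward


def _forward(
    X: np.ndarray,
    weights: NetworkWeights,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (probabilities, cache for backprop).

    Dropout (inverted: surviving units scaled by 1/(1-rate)) is applied to
    hidden activations only when an rng is supplied, i.e. at training time.
    """
    a = np.asarray(X, dtype=float)
    zs, raw_acts, acts, drops = [], [], [a], []
    n_hidden = weights.n_layers - 1
    for layer in range(n_hidden):
        z = a @ weights.W[layer] + weights.b[layer]
        raw = activate(weights.hidden_activation, z)
        if dropout > 0.0 and rng is not None:
            keep = (rng.random(raw.shape) >= dropout) / (1.0 - dropout)
            a = raw * keep
            drops.append(keep)
        else:
            a = raw
            drops.append(None)
        zs.append(z)
        raw_acts.append(raw)
        acts.append(a)
    z_out = a @ weights.W[-1] + weights.b[-1]
    p = activate("sigmoid", z_out)
    return p, (zs, raw_acts, acts, drops)


def predict(
    features: np.ndarray,
    weights: NetworkWeights,
    arch: ArchitectureConfig | None = None,
) -> np.ndarray:
    """Deterministic forward pass (dropout off); per-task sigmoid outputs."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.W[0].shape[0]:
        raise ValueError(
            f"feature matrix with {X.shape[1] if X.ndim == 2 else '?'} columns "
            f"does not match network input size {weights.W[0].shape[0]}"
        )
    p, _ = _forward(X, weights)
    return p


def gradients(
    X: np.ndarray,
    labels: TaskLabelMatrix,
    weights: NetworkWeights,
    penalty: str = "none",
    penalty_weight: float = 0.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Analytic gradients of the masked BCE (plus penalty) wrt all weights
    and biases; returns (loss, dW list, db list)."""
    mask = labels.mask
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed labels in batch")
    p, (zs, raw_acts, acts, drops) = _forward(X, weights, dropout=dropout, rng=rng)
    y = np.where(mask, labels.values, 0.0)
    p_c = np.clip(p, EPS, 1.0 - EPS)
    cell = -(y * np.log(p_c) + (1.0 - y) * np.log(1.0 - p_c))
    loss = float(cell[mask].sum() / n_obs) + _penalty_value(
        weights, penalty, penalty_weight
    )

    # sigmoid + BCE: dL/dz_out = (p - y) on observed cells, 0 elsewhere
    delta = np.where(mask, p - y, 0.0) / n_obs
    dW = [np.empty(0)] * weights.n_layers
    db = [np.empty(0)] * weights.n_layers
    for layer in range(weights.n_layers - 1, -1, -1):
        a_prev = acts[layer]
        dW[layer] = a_prev.T @ delta
        db[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ weights.W[layer].T
            if drops[layer - 1] is not None:
                delta = delta * drops[layer - 1]
            delta = delta * activate_grad(
                weights.hidden_activation, zs[layer - 1], raw_acts[layer - 1]
            )
    if penalty == "L1":
        for layer in range(weights.n_layers):
            dW[layer] = dW[layer] + penalty_weight * np.sign(weights.W[layer])
    elif penalty == "L2":
        for layer in range(weights.n_layers):
            dW[layer] = dW[layer] + 2.0 * penalty_weight * weights.W[layer]
    return loss, dW, db


# ---------------------------------------------------------------------------
# optimizer update rules


class _Update:
    """Stateful per-parameter update rule."""

    def __init__(self, name: str, lr: float, shapes):
        self.name = name
        self.lr = lr
        self.t = 0
        if name in ("adam",):
            self.m = [np.zeros(s) for s in shapes]
            self.v = [np.zeros(s) for s in shapes]
        elif name in ("rmsprop", "adagrad"):
            self.v = [np.zeros(s) for s in shapes]
        elif name != "sgd":
            raise ValueError(f"unknown optimizer {name!r}")

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        eps = 1e-8
        if self.name == "sgd":
            for p, g in zip(params, grads):
                p -= self.lr * g
        elif self.name == "adam":
            b1, b2 = 0.9, 0.999
            for i, (p, g) in enumerate(zip(params, grads)):
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1**self.t)
                vhat = self.v[i] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        elif self.name == "rmsprop":
            rho = 0.9
            for i, (p, g) in enumerate(zip(params, grads)):
                self.v[i] = rho * self.v[i] + (1 - rho) * g * g
                p -= self.lr * g / (np.sqrt(self.v[i]) + eps)
        elif self.name == "adagrad":
            for i, (p, g) in enumerate(zip(params, grads)):
                self.v[i] += g * g
                p -= self.lr * g / (np.sqrt(self.v[i]) + eps)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    """Fixed (non-tuned) training settings plus the seed."""

    batch_size: int = 128
    epochs: int = 50
    learning_rate: float = 1e-3
    penalty: str = "none"
    penalty_weight: float = 1e-4
    dropout: float = 0.0
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def from_architecture(
        cls, arch: ArchitectureConfig, seed: int = 0
    ) -> "TrainingConfig":
        return cls(
            epochs=int(arch["epochs"]),
            learning_rate=float(arch["learning_rate"]),
            penalty=str(arch["penalty"]),
            dropout=float(arch["dropout"]),
            optimizer=str(arch["optimizer"]),
            seed=seed,
        )


def train(
    features: np.ndarray,
    labels: TaskLabelMatrix,
    arch: ArchitectureConfig,
    cfg: TrainingConfig,
    record_loss: list[float] | None = None,
) -> NetworkWeights:
    """Mini-batch training of the architecture described by ``arch``.

    The hidden-layer widths, activation, learning rate, epoch count,
    dropout, optimizer and penalty all come from the architecture; batch
    size, penalty coefficient and the seed come from ``cfg``.  Training is
    deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != labels.n_samples:
        raise ValueError("feature rows must match label rows")
    rng = np.random.default_rng(cfg.seed)
    hidden = arch.effective_hidden_layers()
    weights = init_weights(
        X.shape[1],
        hidden,
        labels.n_tasks,
        rng,
        hidden_activation=str(arch.get("activation", "relu")),
    )
    update = _Update(
        cfg.optimizer,
        cfg.learning_rate,
        [w.shape for w in weights.W] + [b.shape for b in weights.b],
    )
    n = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_labels = labels.subset(idx)
            if not batch_labels.mask.any():
                continue
            loss, dW, db = gradients(
                X[idx],
                batch_labels,
                weights,
                penalty=cfg.penalty,
                penalty_weight=cfg.penalty_weight,
                dropout=cfg.dropout,
                rng=rng if cfg.dropout > 0 else None,
            )
            if record_loss is not None:
                record_loss.append(loss)
            update.step(weights.W + weights.b, dW + db)
    return weights
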