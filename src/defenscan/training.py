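"""Losses, class weighting, stratified splitting, and the training loop.

Four training regimes are supported, selected by :class:`LossSpec`:
plain weighted cross-entropy, label smoothing, an entropy-hinge
confidence penalty, and the DOC one-vs-rest sigmoid loss.  Class
imbalance is handled by weighting each sample with N / (n_c * k).
Optimization is Adam (lr 0.001) for up to 150 epochs with a multi-step
learning-rate decay (factor 0.9) and early stopping (patience 20) that
arms only after a third of the epoch budget has passed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import DefenseClassifier, ModelConfig
from .nn import Adam, Tensor, lr_at_epoch

DEFAULT_MILESTONES = [3, 12, 22, 32, 42, 52, 62, 72, 82, 92]
PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class LossSpec:
    """Which training loss to use and its parameters.

    method: one of softmax_ce, label_smoothing, confidence_penalty, doc.
    beta: weight of the entropy hinge (confidence_penalty only).
    omega: entropy threshold in nats below which confidence is penalized;
        omega = 0 turns the penalty off, recovering plain cross-entropy.
    epsilon: label-smoothing weight; mu is the smoothing distribution over
        the k labels (uniform 1/k when None).
    """

    method: str = "softmax_ce"
    beta: float = 0.1
    omega: float | None = None   # default 0.5 * ln k, resolved at use
    epsilon: float = 0.1
    mu: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in ("softmax_ce", "label_smoothing", "confidence_penalty", "doc"):
            raise ValueError(f"unknown loss method {self.method!r}")
        if self.beta < 0 or self.epsilon < 0 or self.epsilon > 1:
            raise ValueError("beta must be >= 0 and epsilon in [0, 1]")

    @property
    def output_head(self) -> str:
        return "sigmoid" if self.method == "doc" else "softmax"

    def resolved_omega(self, k: int) -> float:
        return 0.5 * math.log(k) if self.omega is None else self.omega


@dataclass
class TrainConfig:
    lr: float = 0.001
    epochs: int = 150
    patience: int = 20
    early_stop_start_fraction: float = 1 / 3
    lr_factor: float = 0.9
    lr_milestones: list[int] = field(default_factory=lambda: list(DEFAULT_MILESTONES))
    ensemble_size: int = 3
    batch_size: int = 64

    def __post_init__(self):
        if self.lr <= 0 or self.patience < 1 or self.ensemble_size < 1:
            raise ValueError("lr > 0, patience >= 1, ensemble_size >= 1 required")

    @property
    def armed_epoch(self) -> int:
        return math.ceil(self.epochs * self.early_stop_start_fraction)


@dataclass
class SplitPlan:
    folds: list[dict[str, np.ndarray]]   # each: {"train": idx, "val": idx, "test": idx}
    n_folds: int
    seed: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Class weights and splits
# ---------------------------------------------------------------------------

def compute_class_weights(class_counts: dict) -> dict:
    """w_c = N / (n_c * k): total samples over class size times class count."""
    if not class_counts:
        raise ValueError("no classes given")
    for c, n in class_counts.items():
        if n < 1:
            raise ValueError(f"class {c!r} has no samples")
    N = sum(class_counts.values())
    k = len(class_counts)
    return {c: N / (n * k) for c, n in class_counts.items()}


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `targets` (each within 1)."""
    base = np.floor(targets).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(targets - base))
    base[order[:rem]] += 1
    return base


def stratified_split(labels, test_frac: float = 0.1, val_frac: float = 0.1,
                     n_folds: int = 10, seed: int = 0) -> SplitPlan:
    """Stratified cross-validation plan with the published rounding convention.

    Per fold: test = floor(test_frac * N) samples, validation = nearest
    integer of val_frac * (N - test), train = remainder; each class is
    represented within +/-1 sample of its global proportion in each part.
    """
    labels = np.asarray(labels)
    N = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    warns = [f"class {c!r} has {n} < {n_folds} members"
             for c, n in zip(classes, counts) if n < n_folds]

    n_test = int(math.floor(test_frac * N))
    n_val = int(round(val_frac * (N - n_test)))
    test_per_class = _largest_remainder(counts * (n_test / N), n_test)
    rng = np.random.default_rng(seed)
    class_indices = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        class_indices[c] = idx

    folds = []
    for f in range(n_folds):
        test_idx, rest_parts = [], []
        for c, n_c, t_c in zip(classes, counts, test_per_class):
            idx = class_indices[c]
            start = int(round(f * n_c / n_folds))
            rolled = np.roll(idx, -start)
            test_idx.append(rolled[:t_c])
            rest_parts.append(rolled[t_c:])
        rest_counts = np.array([len(r) for r in rest_parts])
        val_per_class = _largest_remainder(rest_counts * (n_val / rest_counts.sum()), n_val)
        val_idx = [r[:v] for r, v in zip(rest_parts, val_per_class)]
        train_idx = [r[v:] for r, v in zip(rest_parts, val_per_class)]
        folds.append({
            "test": np.sort(np.concatenate(test_idx)),
            "val": np.sort(np.concatenate(val_idx)),
            "train": np.sort(np.concatenate(train_idx)),
        })
    return SplitPlan(folds=folds, n_folds=n_folds, seed=seed, warnings=warns)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats; 0*log(0) is 0."""
    p = np.asarray(p, dtype=np.float64)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def probs_to_logits(probs: np.ndarray, output_head: str) -> np.ndarray:
    """Invert the output head on clamped probabilities (for probability-space input)."""
    p = np.clip(np.asarray(probs, dtype=np.float64), PROB_FLOOR, 1.0 - PROB_FLOOR)
    if output_head == "sigmoid":
        return np.log(p) - np.log1p(-p)
    return np.log(p)


def _log_softmax(z: Tensor) -> Tensor:
    m = Tensor(z.data.max(axis=1, keepdims=True))
    zs = z - m
    lse = zs.exp().sum(axis=1, keepdims=True).log()
    return zs - lse


def _entropy_t(logp: Tensor) -> Tensor:
    return -(logp.exp() * logp).sum(axis=1)


def _softplus(z: Tensor) -> Tensor:
    sgn = Tensor(np.sign(z.data))
    az = z * sgn
    return z.relu() + ((-az).exp() + 1.0).log()


def loss_fn(logits: Tensor, targets: np.ndarray, class_weights: np.ndarray,
            spec: LossSpec) -> Tensor:
    """Weighted training loss (scalar Tensor) for a batch of logits.

    `class_weights` is a length-k vector; each sample is weighted by the
    weight of its target class, and the batch loss is the weighted mean.
    """
    targets = np.asarray(targets)
    B, k = logits.shape
    w = np.asarray(class_weights, dtype=np.float64)[targets]
    w_t = Tensor(w / w.sum())

    if spec.method == "doc":
        t = np.zeros((B, k))
        t[np.arange(B), targets] = 1.0
        # BCE from logits: t*softplus(-z) + (1-t)*softplus(z), summed over sigmoids
        per = (Tensor(t) * _softplus(-logits) + Tensor(1.0 - t) * _softplus(logits)).sum(axis=1)
        return (w_t * per).sum()

    logp = _log_softmax(logits)
    if spec.method == "label_smoothing" and spec.epsilon > 0:
        mu = np.full(k, 1.0 / k) if spec.mu is None else np.asarray(spec.mu, dtype=np.float64)
        q = np.full((B, k), 0.0)
        q[np.arange(B), targets] = 1.0
        q = (1.0 - spec.epsilon) * q + spec.epsilon * mu[None, :]
        per = -(Tensor(q) * logp).sum(axis=1)
    else:
        per = -logp[np.arange(B), targets]

    if spec.method == "confidence_penalty" and spec.beta > 0:
        omega = spec.resolved_omega(k)
        hinge = (Tensor(np.full(B, omega)) - _entropy_t(logp)).relu()
        per = per + spec.beta * hinge
    return (w_t * per).sum()


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """Encoded, standardized arrays ready for the model."""

    onehot: np.ndarray
    lengths: np.ndarray
    descriptors: np.ndarray
    labels: np.ndarray
    classes: list[str]

    def subset(self, idx: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(self.onehot[idx], self.lengths[idx], self.descriptors[idx],
                            self.labels[idx], self.classes)

    def __len__(self):
        return len(self.labels)


class EarlyStopper:
    """Minimum-validation-loss early stopping, armed only after `armed_epoch`.

    Ties keep the earlier epoch; `update` returns True when training
    should stop (epoch >= armed_epoch and no improvement for `patience`
    epochs).
    """

    def __init__(self, patience: int, armed_epoch: int):
        self.patience = patience
        self.armed_epoch = armed_epoch
        self.best_loss = math.inf
        self.best_epoch = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
        return epoch >= self.armed_epoch and (epoch - self.best_epoch) >= self.patience


def _eval_loss(model: DefenseClassifier, data: ArrayDataset, class_weights: np.ndarray,
               spec: LossSpec) -> float:
    logits = model.predict_logits(data.onehot, data.lengths, data.descriptors)
    return loss_fn(Tensor(logits), data.labels, class_weights, spec).item()


def train_model(train: ArrayDataset, val: ArrayDataset, model_config: ModelConfig,
                train_config: TrainConfig, loss_spec: LossSpec, seed: int = 0
                ) -> tuple[DefenseClassifier, dict]:
    """Train one model; returns it (best-validation weights restored) and a history.

    History records per-epoch train/val loss and the learning rate in force.
    """
    k = len(train.classes)
    counts = {c: int((train.labels == i).sum()) for i, c in enumerate(train.classes)}
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"class {c!r} absent from training split")
    weights_map = compute_class_weights(counts)
    class_weights = np.array([weights_map[c] for c in train.classes])

    cfg = ModelConfig(**{**model_config.__dict__, "k": k,
                         "output_head": loss_spec.output_head})
    model = DefenseClassifier(cfg, seed=seed)
    params = model.parameters()
    opt = Adam(params, lr=train_config.lr)
    rng = np.random.default_rng(seed)
    stopper = EarlyStopper(train_config.patience, train_config.armed_epoch)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    best_state = model.state()

    n = len(train)
    for epoch in range(1, train_config.epochs + 1):
        opt.lr = lr_at_epoch(epoch, train_config.lr, train_config.lr_factor,
                             train_config.lr_milestones)
        order = rng.permutation(n)
        total, wsum = 0.0, 0
        for i in range(0, n, train_config.batch_size):
            idx = order[i:i + train_config.batch_size]
            logits = model.forward(train.onehot[idx], train.lengths[idx],
                                   train.descriptors[idx])
            loss = loss_fn(logits, train.labels[idx], class_weights, loss_spec)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (method={loss_spec.method})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            wsum += len(idx)
        val_loss = _eval_loss(model, val, class_weights, loss_spec)
        history["epoch"].append(epoch)
        history["train_loss"].append(total / max(wsum, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < stopper.best_loss:
            best_state = model.state()
        if stopper.update(epoch, val_loss):
            break
    model.load_state(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["best_val_loss"] = stopper.best_loss
    return model, history


def train_ensemble(train: ArrayDataset, val: ArrayDataset, model_config: ModelConfig,
                   train_config: TrainConfig, loss_spec: LossSpec,
                   seeds: list[int] | None = None
                   ) -> tuple[list[DefenseClassifier], list[dict]]:
    """Independently train `ensemble_size` members from different random seeds."""
    if seeds is None:
        seeds = list(range(train_config.ensemble_size))
    if len(seeds) != train_config.ensemble_size:
        raise ValueError("len(seeds) must equal ensemble_size")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds in ensemble: members will be identical")
    models, histories = [], []
    for s in seeds:
        m, h = train_model(train, val, model_config, train_config, loss_spec, seed=s)
        models.append(m)
        histories.append(h)
    return models, histories
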