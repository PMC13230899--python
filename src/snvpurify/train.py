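"""Fitting the correction network to (features, true count) pairs.

The trainer minimises a regression loss on the log1p-transformed true count
with Adam, early-stops on validation loss, and returns the parameters of
the best-validation epoch. The train/validation split is stratified over
the five purity bins used in evaluation so both sides see the full purity
gradient.

Training is deterministic: a fixed ``TrainConfig.seed`` fixes the split,
the weight initialisation, the batch order and the dropout masks, giving
bitwise-identical loss histories across runs at a fixed thread count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor
from .features import GROUP_NAMES, FeatureGroupSet
from .model import CorrectionModel, FeatureScaler, ModelConfig

logger = logging.getLogger(__name__)

#: purity bin edges shared with evaluate (left-open, right-closed)
PURITY_BIN_EDGES = (0.2, 0.3, 0.5, 0.7, 0.8, 1.0)

LOSSES = ("mse_log1p", "mse", "huber")


@dataclass
class TrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 60
    val_fraction: float = 0.2
    loss: str = "mse_log1p"
    huber_delta: float = 1.0
    cosine_schedule: bool = True
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int


class Adam:
    """Adaptive moment estimation with decoupled weight decay.

    Decay applies only to weight matrices (names ending in a ``W``-style
    parameter); biases, LayerNorm parameters, gates' biases and position
    embeddings are exempt, so e.g. a constant target can be represented by
    decayed-to-zero weights plus a head bias.
    """

    def __init__(self, params: Mapping[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._decayed = {k for k, p in params.items()
                         if p.data.ndim == 2 and "ln" not in k}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k in self._decayed:
                p.data -= lr * self.weight_decay * p.data


def _purity_bin_index(purity: np.ndarray) -> np.ndarray:
    """Map purities to bin 0..4 ((0.2,0.3], ..., (0.8,1.0]); out-of-range
    values are clipped into the nearest bin for stratification purposes."""
    edges = np.asarray(PURITY_BIN_EDGES)
    idx = np.searchsorted(edges, purity, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def split_cohort(
    purities: Sequence[float], val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Purity-stratified train/validation index split.

    Each of the five evaluation purity bins contributes proportionally to
    the validation set when populated; bins with a single sample are merged
    into the neighbouring bin. Deterministic under ``seed``.
    """
    purities = np.asarray(purities, dtype=np.float64)
    n = purities.size
    if n < 2:
        raise ValueError("cohort must contain at least 2 samples to split")
    if val_fraction == 0.0:
        return np.arange(n), np.array([], dtype=np.int64)
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng([seed, 21])
    bins = _purity_bin_index(purities)
    # merge singleton bins into their lower (or upper) neighbour
    for b in range(5):
        members = np.flatnonzero(bins == b)
        if members.size == 1:
            neighbour = b - 1 if b > 0 else b + 1
            logger.warning("purity bin %d has a single sample; merging into bin %d",
                           b, neighbour)
            bins[members] = neighbour
    train_idx, val_idx = [], []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(members.size)]
        n_val = int(round(val_fraction * members.size))
        n_val = min(max(n_val, 1), members.size - 1)
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    train_idx = np.sort(np.array(train_idx, dtype=np.int64))
    val_idx = np.sort(np.array(val_idx, dtype=np.int64))
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("split left one side empty; adjust val_fraction")
    return train_idx, val_idx


def _target_transform(counts: np.ndarray, log1p: bool) -> np.ndarray:
    return np.log1p(counts) if log1p else counts.astype(np.float64)


def _batch_loss(model: CorrectionModel, groups: Mapping[str, np.ndarray],
                target: np.ndarray, loss: str, huber_delta: float) -> Tensor:
    pred = model.forward(groups)  # log1p scale when configured
    t = Tensor(target)
    if loss == "mse_log1p" or (loss == "mse" and not model.config.log1p_target):
        diff = pred - t
        return (diff * diff).mean()
    if loss == "mse":  # count-scale loss through the expm1 inverse transform
        diff = (pred.exp() - 1.0) - t
        return (diff * diff).mean()
    # huber on the model's target scale
    diff = (pred - t).abs()
    d = huber_delta
    quad = diff * diff * 0.5
    lin = diff * d - 0.5 * d * d
    mask = (diff.data <= d).astype(np.float64)
    return (quad * Tensor(mask) + lin * Tensor(1.0 - mask)).mean()


def _epoch_loss(model: CorrectionModel, groups: Mapping[str, np.ndarray],
                target: np.ndarray, cfg: TrainConfig) -> float:
    """Full-set loss in inference mode (no dropout, no graph retention)."""
    loss = _batch_loss(model, groups, target, cfg.loss, cfg.huber_delta)
    return float(loss.data)


def _subset(groups: Mapping[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {g: m[idx] for g, m in groups.items()}


def fit(
    model: CorrectionModel,
    samples: Sequence[FeatureGroupSet],
    true_counts: Sequence[int],
    purities: Sequence[float],
    config: TrainConfig | None = None,
) -> tuple[CorrectionModel, TrainHistory]:
    """Train ``model`` in place; returns (model at best checkpoint, history).

    The feature scaler is fitted on the training split, the regression-head
    bias is initialised so the initial prediction equals the mean training
    target, and the best-validation parameters are restored before return.
    With ``val_fraction == 0`` no validation split is made and the final
    epoch's parameters are kept (used for capacity/overfit checks).
    """
    cfg = config or TrainConfig()
    samples = list(samples)
    counts = np.asarray(true_counts, dtype=np.float64)
    purities = np.asarray(purities, dtype=np.float64)
    if not (len(samples) == counts.size == purities.size):
        raise ValueError("samples, true_counts and purities must be aligned")

    groups_all = CorrectionModel.batch_groups(samples)
    for i, g in enumerate(GROUP_NAMES[: model.config.n_groups]):
        if groups_all[g].shape[1] != model.config.group_input_dims[i]:
            raise ValueError(
                f"group {g!r} dimension {groups_all[g].shape[1]} does not match "
                f"model config {model.config.group_input_dims[i]}"
            )
    target_all = _target_transform(counts, model.config.log1p_target)

    train_idx, val_idx = split_cohort(purities, cfg.val_fraction, cfg.seed)
    has_val = val_idx.size > 0
    groups_tr, target_tr = _subset(groups_all, train_idx), target_all[train_idx]
    groups_val, target_val = _subset(groups_all, val_idx), target_all[val_idx]

    # standardize features on the training split
    model.scaler = FeatureScaler.fit(groups_tr)
    # head bias init: softplus(b) == mean target  =>  b = softplus^{-1}(mean)
    mean_t = float(target_tr.mean())
    model.params["head.b"].data[:] = (
        np.log(np.expm1(mean_t)) if mean_t > 1e-8 else mean_t
    )

    rng = np.random.default_rng([cfg.seed, 22])
    model._dropout_rng = np.random.default_rng([cfg.seed, 23])
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    n_tr = train_idx.size
    history = TrainHistory(train_loss=[], val_loss=[], best_epoch=-1)
    best_val = np.inf
    best_state = model.state_copy()
    bad_epochs = 0

    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate
        if cfg.cosine_schedule:
            lr *= 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.max_epochs))
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            loss = _batch_loss(model, _subset(groups_tr, idx), target_tr[idx],
                               cfg.loss, cfg.huber_delta)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss.backward()
            opt.step(lr=lr)

        model._dropout_rng, dr = None, model._dropout_rng
        tr_loss = _epoch_loss(model, groups_tr, target_tr, cfg)
        val_loss = _epoch_loss(model, groups_val, target_val, cfg) if has_val else tr_loss
        model._dropout_rng = dr
        history.train_loss.append(tr_loss)
        history.val_loss.append(val_loss)

        monitored = val_loss if has_val else tr_loss
        if monitored < best_val:
            best_val = monitored
            best_state = model.state_copy()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if has_val and bad_epochs >= cfg.patience:
                logger.info("early stopping at epoch %d (best %d)", epoch, history.best_epoch)
                break

    model._dropout_rng = None
    if has_val:
        model.load_state(best_state)
    else:
        history.best_epoch = len(history.train_loss) - 1
    return model, history


def fit_new(
    samples: Sequence[FeatureGroupSet],
    true_counts: Sequence[int],
    purities: Sequence[float],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[CorrectionModel, TrainHistory]:
    """Convenience wrapper: build a fresh model (seeded from the train
    config when no model config is given) and fit it."""
    if model_config is None:
        seed = train_config.seed if train_config is not None else 0
        model_config = ModelConfig(seed=seed)
    model = CorrectionModel(model_config)
    return fit(model, samples, true_counts, purities, train_config)
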