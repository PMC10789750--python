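"""Losses, NMR pretraining, and LSF fine-tuning.

The classification loss is binary cross-entropy over atoms, optionally
weighted by one of three class-imbalance schemes whose shared idea is that
the weight of a correct class prediction is inversely related to how often
that class is predicted: a model that rarely predicts "reactive" earns a
large reward for a correct reactive call and a small one for yet another
correct unreactive call. Weights are computed from hard (thresholded)
predictions and batch-level class ratios, and are treated as constants with
respect to the gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .datasets import (ConditionVocabulary, NMRRecord, ReactionRecord,
                       encode_conditions)
from .errors import ConfigError, LossError, TrainingError
from .model import (ModelConfig, ModelParams, forward_reactivity,
                    forward_shifts, init_params, transfer_trunk)

log = logging.getLogger(__name__)

LOSS_VARIANTS = ("plain", "w1", "w2", "w3")


@dataclass
class LossInputs:
    """Per-atom predicted probabilities, 0/1 truth, and weights."""

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if not (self.x.shape == self.y.shape == self.w.shape):
            raise LossError("x, y, w must have identical shapes")
        if not np.all((self.y == 0) | (self.y == 1)):
            raise LossError("y must be 0/1")


@dataclass
class ClassRatios:
    """Batch-level fractions of predicted and true positives.

    ``pred_p`` is the fraction of all atoms in the batch predicted positive
    (1 means the model predicts every site reacts, 0 that nothing does);
    ``true_p`` is the fraction labeled positive. Both are clamped into
    [eps, 1-eps] so their logs stay finite.
    """

    pred_p: float
    true_p: float
    eps: float = 1e-6

    def __post_init__(self):
        self.pred_p = float(np.clip(self.pred_p, self.eps, 1 - self.eps))
        self.true_p = float(np.clip(self.true_p, self.eps, 1 - self.eps))


def compute_class_ratios(probabilities: np.ndarray, labels: np.ndarray,
                         tau: float = 0.5, eps: float = 1e-6) -> ClassRatios:
    hard = classify(probabilities, tau)
    return ClassRatios(pred_p=float(np.mean(hard)),
                       true_p=float(np.mean(labels)), eps=eps)


def classify(probabilities: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Hard labels 1[p > tau]."""
    return (np.asarray(probabilities) > tau).astype(np.float64)


def bce_loss(inputs: LossInputs, eps: float = 1e-6) -> float:
    """Weighted binary cross-entropy, minimization sign convention.

    -sum_i w_i * (y_i log x_i + (1 - y_i) log(1 - x_i)); with all weights 1
    this is the standard (sum-reduced) binary cross-entropy.
    """
    x = np.clip(inputs.x, eps, 1 - eps)
    if np.any(inputs.x < 0) or np.any(inputs.x > 1):
        raise LossError("predicted probabilities outside [0, 1]")
    y = inputs.y
    return float(-np.sum(inputs.w * (y * np.log(x)
                                     + (1 - y) * np.log(1 - x))))


def _w1_bracket(x: np.ndarray, y: np.ndarray, lp: float, l1p: float,
                lt: float, l1t: float) -> np.ndarray:
    return (x * y * lp + (1 - y) * (1 - x) * l1p
            + (1 - y) * x * lt + y * (1 - x) * l1t)


def _w2_bracket(x: np.ndarray, y: np.ndarray, lp: float, l1p: float,
                lt: float, l1t: float) -> np.ndarray:
    return (y * x * lt + (1 - y) * (1 - x) * l1t
            + (1 - y) * x * l1p + y * x * lp)


def bce_weight(variant: int, x: np.ndarray, y: np.ndarray,
               ratios: ClassRatios) -> np.ndarray:
    """Per-atom loss weight, schemes 1-3.

    ``x`` must be the hard thresholded prediction (0/1). Each scheme is an
    algebraic combination of {x, y, log pred_p, log true_p} terms; the log
    magnitudes -log(.) >= 0 are used so that the rarer a predicted class,
    the larger the weight it carries. Scheme 2 adds a second bracket of
    cross terms to scheme 1's, and scheme 3 is scheme 2 with the first
    bracket counted twice. Weights never feed back into the gradient.

    Raises
    ------
    ConfigError
        If ``variant`` is not 1, 2 or 3.
    """
    if variant not in (1, 2, 3):
        raise ConfigError(f"weight variant must be 1, 2 or 3, got {variant}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lp = -np.log(ratios.pred_p)
    l1p = -np.log(1 - ratios.pred_p)
    lt = -np.log(ratios.true_p)
    l1t = -np.log(1 - ratios.true_p)
    first = _w1_bracket(x, y, lp, l1p, lt, l1t)
    if variant == 1:
        return first
    second = _w2_bracket(x, y, lp, l1p, lt, l1t)
    coeff = 2.0 if variant == 3 else 1.0
    return coeff * first + second


@dataclass
class TrainConfig:
    """Everything that determines a training trajectory."""

    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-4
    seed: int = 0
    loss_variant: str = "w1"      # plain | w1 | w2 | w3
    transfer: str = "transfer"    # scratch | transfer
    freeze_trunk: bool = False    # freeze the trunk for the whole run
    freeze_epochs: int = 0        # warmup epochs with the trunk frozen
    unfreeze_lr_scale: float = 1.0  # lr multiplier once the trunk unfreezes
    lr_schedule: str = "constant"   # constant | cosine (decay to lr/10)
    tau: float = 0.5              # classification threshold
    eps: float = 1e-6
    hidden: int = 200
    rounds: int = 4
    universal_node: bool = True
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.loss_variant not in LOSS_VARIANTS:
            raise ConfigError(f"loss variant {self.loss_variant!r} not in "
                              f"{LOSS_VARIANTS}")
        if self.transfer not in ("scratch", "transfer"):
            raise ConfigError(f"transfer mode {self.transfer!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ConfigError(f"lr schedule {self.lr_schedule!r}")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "constant" or self.epochs <= 1:
            return self.lr
        t = epoch / (self.epochs - 1)
        return self.lr * (0.1 + 0.45 * (1 + np.cos(np.pi * t)))

    def model_config(self, cond_dim: int = 0, **extra) -> ModelConfig:
        return ModelConfig(hidden=self.hidden, rounds=self.rounds,
                           universal_node=self.universal_node,
                           cond_dim=cond_dim, seed=self.seed, **extra)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


def pretrain_nmr(records: list[NMRRecord], cfg: TrainConfig) -> ModelParams:
    """Train trunk + shift head by MSE on per-carbon 13C shifts.

    A ``val_fraction`` holdout is split off for per-epoch MAE logging
    (stored in ``params.history``).

    Raises
    ------
    TrainingError
        On empty input or NaN loss (divergence), reporting the epoch.
    """
    if not records:
        raise TrainingError("no NMR records")
    all_ppm = np.concatenate([list(r.shifts.values()) for r in records])
    shift_mean = float(np.mean(all_ppm))
    shift_scale = float(np.std(all_ppm) + 1e-9)
    params = init_params(ModelConfig(
        hidden=cfg.hidden, rounds=cfg.rounds,
        universal_node=cfg.universal_node, seed=cfg.seed,
        shift_mean=shift_mean, shift_scale=shift_scale))
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(records)))
    order = rng.permutation(len(records))
    val = [records[i] for i in order[:n_val]]
    train = [records[i] for i in order[n_val:]] or list(records)

    keys = params.trunk_keys() + params.head_keys("nmr")
    opt = Adam(params.parameters(keys), lr=cfg.lr)
    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for batch in _batches(len(train), cfg.batch_size, rng):
            opt.zero_grad()
            loss = Tensor(0.0)
            n_obs = 0
            for idx in batch:
                rec = train[idx]
                pred = forward_shifts(rec.graph, params)
                carbons = np.array(sorted(rec.shifts))
                target = np.array(
                    [[(rec.shifts[i] - shift_mean) / shift_scale]
                     for i in carbons])
                diff = pred.rows(carbons) - Tensor(target)
                loss = loss + (diff * diff).sum()
                n_obs += len(carbons)
            loss = loss * (1.0 / max(n_obs, 1))
            if not np.isfinite(loss.data):
                raise TrainingError(f"NaN loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        val_mae = validate_nmr(params, val) if val else float("nan")
        params.history.append({"epoch": epoch, "train_loss": epoch_loss,
                               "val_mae_ppm": val_mae})
        log.info("NMR epoch %d: loss=%.4f val MAE=%.2f ppm",
                 epoch, epoch_loss, val_mae)
    return params


def validate_nmr(params: ModelParams, records: list[NMRRecord]) -> float:
    """Mean absolute shift error (ppm) over all assigned carbons."""
    from .model import predict_shifts
    errs = []
    for rec in records:
        pred = predict_shifts(rec.graph, params)
        errs.extend(abs(pred[i] - ppm) for i, ppm in rec.shifts.items())
    return float(np.mean(errs)) if errs else float("nan")


def _loss_weights(probs: np.ndarray, y: np.ndarray,
                  cfg: TrainConfig) -> np.ndarray:
    if cfg.loss_variant == "plain":
        return np.ones_like(y)
    hard = classify(probs, cfg.tau)
    ratios = ClassRatios(pred_p=float(np.mean(hard)),
                         true_p=float(np.mean(y)), eps=cfg.eps)
    return bce_weight(int(cfg.loss_variant[1]), hard, y, ratios)


def finetune_lsf(init: ModelParams | None, records: list[ReactionRecord],
                 vocab: ConditionVocabulary,
                 cfg: TrainConfig) -> ModelParams:
    """Fine-tune the reactivity classifier on labeled reaction records.

    ``transfer`` mode loads the trunk from ``init`` (an NMR checkpoint)
    and reinitializes the LSF head; ``scratch`` mode ignores ``init``
    entirely (the ablation baseline). Each record must carry labels.

    Raises
    ------
    TransferError
        If ``init``'s trunk shapes are incompatible.
    TrainingError
        On missing labels or NaN loss.
    """
    if not records:
        raise TrainingError("no reaction records")
    if any(r.labels is None for r in records):
        raise TrainingError("all records need reactive-site labels")
    params = init_params(cfg.model_config(cond_dim=vocab.length))
    if cfg.transfer == "transfer":
        if init is None:
            raise TrainingError("transfer mode requires an init checkpoint")
        transfer_trunk(init, params)
        params.config.shift_mean = init.config.shift_mean
        params.config.shift_scale = init.config.shift_scale

    prepared = [(r.sm, encode_conditions(r.conditions, vocab),
                 np.asarray(r.labels.labels, dtype=np.float64))
                for r in records]
    # Prior-logit bias init: the head starts out predicting the base rate
    # of reactive atoms instead of ~0.5, the standard remedy for the
    # all-negative collapse on heavily imbalanced atom labels.
    base_rate = float(np.clip(np.mean(np.concatenate(
        [y for _, _, y in prepared])), cfg.eps, 1 - cfg.eps))
    params.tensors["b_l3"].data[:] = np.log(base_rate / (1 - base_rate))
    rng = np.random.default_rng(cfg.seed)
    head_keys = params.head_keys("lsf")
    all_keys = params.trunk_keys() + head_keys
    # Gradual unfreezing: fit the fresh head on the (frozen) pretrained
    # features first, so its early gradients cannot distort the trunk.
    freeze_until = (cfg.epochs if cfg.freeze_trunk
                    else (cfg.freeze_epochs if cfg.transfer == "transfer"
                          else 0))
    opt = Adam(params.parameters(head_keys), lr=cfg.lr)
    lo_clip, hi_clip = cfg.eps, 1 - cfg.eps
    for epoch in range(cfg.epochs):
        if epoch == freeze_until and freeze_until < cfg.epochs:
            opt = Adam(params.parameters(all_keys),
                       lr=cfg.lr * (cfg.unfreeze_lr_scale
                                    if freeze_until > 0 else 1.0))
        if cfg.lr_schedule != "constant":
            opt.lr = cfg.lr_at(epoch)
        epoch_loss = 0.0
        for batch in _batches(len(prepared), cfg.batch_size, rng):
            opt.zero_grad()
            outputs = []
            for idx in batch:
                g, cond, y = prepared[idx]
                outputs.append((forward_reactivity(g, cond, params), y))
            probs = np.concatenate([o.data[:, 0] for o, _ in outputs])
            ys = np.concatenate([y for _, y in outputs])
            w_all = _loss_weights(probs, ys, cfg)
            loss = Tensor(0.0)
            pos = 0
            for out, y in outputs:
                n = len(y)
                w = Tensor(w_all[pos:pos + n].reshape(-1, 1))
                yt = Tensor(y.reshape(-1, 1))
                x = out.clamp(lo_clip, hi_clip)
                term = w * (yt * x.log() + (1.0 - yt) * (1.0 - x).log())
                loss = loss + (-term.sum())
                pos += n
            # Weighted mean: keeps the gradient scale comparable across
            # weighting schemes and batch class compositions.
            loss = loss * (1.0 / max(float(w_all.sum()), cfg.eps))
            if not np.isfinite(loss.data):
                raise TrainingError(f"NaN loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        params.history.append({"epoch": epoch, "train_loss": epoch_loss})
        log.info("LSF epoch %d: loss=%.4f", epoch, epoch_loss)
    return params
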