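"""Training and few-shot fine-tuning loops.

The task loss is Dice + MSE: ``dice_w * (1 - soft Dice over the two
foreground zones)`` plus ``mse_w * MSE(softmax probabilities, one-hot
target)``.  Soft Dice uses an additive smoothing term eps (default 1) in
numerator and denominator, so an empty prediction of an empty zone counts
as perfect.  Optimization is Adam with global-norm gradient clipping;
the learning rate decays by ``lr_decay_factor`` after ``lr_patience``
epochs without validation-loss improvement; training stops early after
``early_stop_patience`` stagnant epochs; the checkpointed weights are the
epoch with the best validation Dice.

During Task-1 training a :class:`TrajectoryBuffer` records per-parameter
movement (for the vEWC stability term) and, at the end, the empirical
Fisher is estimated on a training batch and the final weights become the
anchor theta_old.  ``finetune_task`` draws a small seeded sample from the
new institution's pool (15 slices for 10 epochs by default, at a very low
learning rate), applies the consolidation penalty of the chosen mode, and
refreshes the Fisher state by running-average accumulation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from ._nn import Adam
from .continual import (ImportanceState, TrajectoryBuffer, TransitionConfig,
                        accumulate_fisher, estimate_fisher, penalized_step,
                        penalty_term)
from .model import ModelConfig, ZoneSegNet
from .preprocess import SlicePair, augment

__all__ = [
    "TrainConfig", "FinetuneConfig", "TaskCheckpoint", "combined_loss",
    "soft_dice_loss", "train_task", "finetune_task", "task_transition",
    "evaluate_loss", "mean_foreground_dice",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 8
    grad_clip_norm: float = 1.0
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 25
    seed: int = 0
    dice_weight: float = 1.0
    mse_weight: float = 1.0
    fisher_batch: int = 8

    def validate(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size >= 1 and lr > 0 required")


@dataclasses.dataclass(frozen=True)
class FinetuneConfig:
    n_samples: int = 15
    epochs: int = 10
    lr: float = 1e-5              # "very low" by default
    mode: str = "none"
    lambda_reg: float | None = None
    conservative_augment: bool = True
    batch_size: int = 8
    grad_clip_norm: float = 1.0
    early_stop_patience: int = 25
    seed: int = 0
    dice_weight: float = 1.0
    mse_weight: float = 1.0
    halved_vewc: bool = False

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mode not in ("none", "ewc", "vewc"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class TaskCheckpoint:
    parameters: dict[str, np.ndarray]
    importance: ImportanceState | None
    history: dict
    model_config: ModelConfig
    best_epoch: int
    task_id: str = "task1"

    def build_model(self) -> ZoneSegNet:
        model = ZoneSegNet(self.model_config)
        model.load_state_dict(self.parameters)
        return model

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "parameters.npz", **self.parameters)
        if self.importance is not None:
            self.importance.save(directory / "importance")
        meta = {"task_id": self.task_id, "best_epoch": self.best_epoch,
                "history": self.history,
                "model_config": repr(self.model_config)}
        (directory / "checkpoint.json").write_text(json.dumps(meta, indent=2))


# -- losses ----------------------------------------------------------------

def _onehot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((mask.shape[0], n_classes) + mask.shape[1:])
    for c in range(n_classes):
        out[:, c] = mask == c
    return out


def soft_dice_loss(probs: Tensor, onehot: np.ndarray,
                   eps: float = 1.0) -> Tensor:
    """1 - mean soft Dice over the foreground classes (1: TZ, 2: PZ),
    computed over the whole batch per class."""
    total = Tensor(0.0)
    n_fg = onehot.shape[1] - 1
    for c in range(1, onehot.shape[1]):
        p = probs[:, c]
        g = Tensor(onehot[:, c])
        inter = (p * g).sum()
        denom = p.sum() + g.sum()
        dice = (inter * 2.0 + eps) / (denom + eps)
        total = total + (1.0 - dice)
    return total / float(n_fg)


def combined_loss(scores: Tensor, masks: np.ndarray,
                  dice_weight: float = 1.0, mse_weight: float = 1.0,
                  eps: float = 1.0) -> Tensor:
    """dice_w * soft-Dice loss + mse_w * MSE(softmax, one-hot)."""
    probs = scores.softmax(axis=1)
    onehot = _onehot(masks, scores.shape[1])
    dice = soft_dice_loss(probs, onehot, eps=eps)
    diff = probs - Tensor(onehot)
    mse = (diff * diff).mean()
    return dice * dice_weight + mse * mse_weight


# -- evaluation helpers used inside the loops ------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def evaluate_loss(model: ZoneSegNet, pairs: list[SlicePair],
                  dice_weight: float = 1.0, mse_weight: float = 1.0,
                  batch_size: int = 8) -> float:
    losses, weights = [], []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        imgs = np.stack([p.image for p in chunk])
        masks = np.stack([p.mask for p in chunk])
        loss = combined_loss(model(Tensor(imgs)), masks,
                             dice_weight, mse_weight)
        losses.append(float(loss.item()))
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def mean_foreground_dice(model: ZoneSegNet, pairs: list[SlicePair],
                         batch_size: int = 8) -> float:
    """Mean over slices and foreground zones of the hard Dice overlap
    (both-empty zones count 1)."""
    from .metrics import dsc
    scores = []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        preds = model.predict(np.stack([p.image for p in chunk]))
        for pred, pair in zip(preds, chunk):
            for zone in (1, 2):
                scores.append(dsc(pred, pair.mask, zone))
    return float(np.mean(scores))


def _per_case_losses(model, pairs, dice_w, mse_w) -> dict[int, float]:
    by_case: dict[int, list[SlicePair]] = {}
    for p in pairs:
        by_case.setdefault(p.case_id, []).append(p)
    return {cid: evaluate_loss(model, ps, dice_w, mse_w)
            for cid, ps in sorted(by_case.items())}


# -- main loops ------------------------------------------------------------

def _run_training(model: ZoneSegNet, train_pairs, val_pairs, *,
                  epochs: int, lr: float, batch_size: int,
                  grad_clip_norm: float, lr_decay_factor: float,
                  lr_patience: int, early_stop_patience: int,
                  seed: int, dice_w: float, mse_w: float,
                  state: ImportanceState | None = None,
                  transition: TransitionConfig | None = None,
                  trajectory: TrajectoryBuffer | None = None):
    """Shared epoch loop; returns (history, best_params, best_epoch)."""
    rng = np.random.default_rng(seed)
    params = model.named_parameters()
    optimizer = Adam(params, lr=lr, grad_clip_norm=grad_clip_norm)
    transition = transition or TransitionConfig(mode="none")
    history = {"train_loss": [], "val_loss": [], "val_dice": [], "lr": [],
               "per_case_val_loss": []}
    best = {"dice": -np.inf, "params": model.state_dict(), "epoch": 0}
    best_val_loss, stagnant = np.inf, 0

    for epoch in range(epochs):
        epoch_losses = []
        for idx in _batches(len(train_pairs), batch_size, rng):
            chunk = [train_pairs[i] for i in idx]
            imgs = np.stack([p.image for p in chunk])
            masks = np.stack([p.mask for p in chunk])
            task_loss = combined_loss(model(Tensor(imgs)), masks,
                                      dice_w, mse_w)
            if not np.isfinite(task_loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting")
            total = penalized_step(model, task_loss, state, transition,
                                   optimizer)
            epoch_losses.append(total)
            if trajectory is not None:
                trajectory.update(params)
        val_loss = evaluate_loss(model, val_pairs, dice_w, mse_w, batch_size)
        val_dice = mean_foreground_dice(model, val_pairs, batch_size)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_dice"].append(val_dice)
        history["lr"].append(optimizer.lr)
        history["per_case_val_loss"].append(
            _per_case_losses(model, val_pairs, dice_w, mse_w))
        if val_dice > best["dice"]:
            best = {"dice": val_dice, "params": model.state_dict(),
                    "epoch": epoch}
        if val_loss < best_val_loss - 1e-6:
            best_val_loss, stagnant = val_loss, 0
        else:
            stagnant += 1
            if stagnant % lr_patience == 0:
                optimizer.lr *= lr_decay_factor
            if stagnant >= early_stop_patience:
                break
    return history, best["params"], best["epoch"]


def train_task(model: ZoneSegNet, train_pairs: list[SlicePair],
               val_pairs: list[SlicePair],
               config: TrainConfig = TrainConfig(),
               task_id: str = "task1") -> TaskCheckpoint:
    """Task training: optimize, track parameter trajectories, then estimate
    Fisher scores and snapshot the anchor."""
    config.validate()
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    trajectory = TrajectoryBuffer(model.named_parameters())
    history, best_params, best_epoch = _run_training(
        model, train_pairs, val_pairs,
        epochs=config.epochs, lr=config.lr, batch_size=config.batch_size,
        grad_clip_norm=config.grad_clip_norm,
        lr_decay_factor=config.lr_decay_factor,
        lr_patience=config.lr_patience,
        early_stop_patience=config.early_stop_patience,
        seed=config.seed, dice_w=config.dice_weight,
        mse_w=config.mse_weight, trajectory=trajectory)
    model.load_state_dict(best_params)
    fisher_samples = train_pairs[:config.fisher_batch]
    fisher = estimate_fisher(model, fisher_samples)
    state = ImportanceState(
        theta_old={k: v.data.copy() for k, v in
                   model.named_parameters().items() if not v.frozen},
        fisher=fisher, stability=trajectory.finalize(),
        n_samples=len(fisher_samples))
    return TaskCheckpoint(parameters=best_params, importance=state,
                          history=history, model_config=model.config,
                          best_epoch=best_epoch, task_id=task_id)


def task_transition(checkpoint: TaskCheckpoint,
                    config: TransitionConfig) -> tuple[ZoneSegNet,
                                                       ImportanceState | None]:
    """Initialize Task-2 training: model at theta*_task1, with the stored
    ImportanceState driving the chosen consolidation penalty."""
    config.validate()
    if config.mode != "none" and checkpoint.importance is None:
        raise ValueError("EWC/vEWC transition requires an ImportanceState")
    model = checkpoint.build_model()
    state = checkpoint.importance
    if state is not None and config.lambda_reg is not None:
        state = dataclasses.replace(state, lambda_reg=config.lambda_reg)
    return model, state


def finetune_task(checkpoint: TaskCheckpoint,
                  new_pool: list[SlicePair],
                  val_pairs: list[SlicePair],
                  config: FinetuneConfig = FinetuneConfig(),
                  task_id: str = "task2") -> TaskCheckpoint:
    """Few-shot fine-tuning on a new institution under the chosen
    consolidation mode, then Fisher refresh by running-average
    accumulation."""
    config.validate()
    transition = TransitionConfig(mode=config.mode, eta=config.lr,
                                  rho=config.lr,
                                  lambda_reg=config.lambda_reg,
                                  halved_vewc=config.halved_vewc)
    model, state = task_transition(checkpoint, transition)
    rng = np.random.default_rng(config.seed)
    n = min(config.n_samples, len(new_pool))
    chosen = [new_pool[i] for i in rng.choice(len(new_pool), size=n,
                                              replace=False)]
    train_pairs = augment(chosen, seed=config.seed,
                          conservative=config.conservative_augment)
    trajectory = TrajectoryBuffer(model.named_parameters())
    history, best_params, best_epoch = _run_training(
        model, train_pairs, val_pairs,
        epochs=config.epochs, lr=config.lr, batch_size=config.batch_size,
        grad_clip_norm=config.grad_clip_norm,
        lr_decay_factor=0.5, lr_patience=10,
        early_stop_patience=config.early_stop_patience,
        seed=config.seed, dice_w=config.dice_weight,
        mse_w=config.mse_weight,
        state=state, transition=transition, trajectory=trajectory)
    model.load_state_dict(best_params)
    new_fisher = estimate_fisher(model, chosen[:8])
    if state is not None:
        fisher = accumulate_fisher(state, new_fisher, len(chosen[:8]))
        n_total = state.n_samples + len(chosen[:8])
    else:
        fisher, n_total = new_fisher, len(chosen[:8])
    new_state = ImportanceState(
        theta_old={k: v.data.copy() for k, v in
                   model.named_parameters().items() if not v.frozen},
        fisher=fisher, stability=trajectory.finalize(),
        lambda_reg=(state.lambda_reg if state is not None else 100.0),
        n_samples=n_total)
    return TaskCheckpoint(parameters=best_params, importance=new_state,
                          history=history, model_config=model.config,
                          best_epoch=best_epoch, task_id=task_id)
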