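"""Synchronous continual learning: Fisher information, elastic weight
consolidation (EWC), its stability-augmented variant (vEWC), and the
Task-1 -> Task-2 transition.

After Task 1, each trainable parameter theta_i gets an importance estimate:

* Fisher score  F_i ~ (1/N) sum_n (d log P(y_n|x_n, theta) / d theta_i)^2,
  the empirical Fisher at the observed labels, with log P the per-pixel
  log-softmax probability of the true class summed over pixels;
* stability    S(theta_i) = (1/T) sum_t |theta_{i,t} - theta_{i,t-1}|,
  the mean absolute per-step movement during Task-1 training.

Fine-tuning on Task 2 then minimizes L_task plus a quadratic pull toward
the Task-1 anchor theta_old:

    EWC :  (lambda/2) sum_i F_i (theta_i - theta_i_old)^2
    vEWC:  lambda     sum_i (F_i + S_i) (theta_i - theta_i_old)^2
           (a flag selects the lambda/2 variant of the same penalty)

Parameters important to Task 1 (large F or S) are thereby held near their
old values, mitigating catastrophic forgetting, while unimportant ones
adapt freely.  After Task 2 the Fisher state is refreshed by re-estimation
on Task-2 data and accumulated as a sample-count-weighted running average
with the prior state.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from ._nn import Module, Parameter

__all__ = [
    "ImportanceState", "TrajectoryBuffer", "TransitionConfig",
    "estimate_fisher", "ewc_penalty", "vewc_penalty", "penalty_term",
    "penalized_step", "accumulate_fisher",
]

DEFAULT_LAMBDA = {"ewc": 100.0, "vewc": 50.0}


@dataclasses.dataclass
class ImportanceState:
    """Per-parameter anchor and importance scores, keyed by dotted name.

    Frozen parameters are excluded: they cannot drift, so they need no
    penalty."""
    theta_old: dict[str, np.ndarray]
    fisher: dict[str, np.ndarray]
    stability: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    lambda_reg: float = 100.0
    n_samples: int = 0            # Fisher batch size (for accumulation)

    def validate(self) -> None:
        for k, f in self.fisher.items():
            if np.any(f < 0):
                raise ValueError(f"negative Fisher score for {k}")
        for k, s in self.stability.items():
            if np.any(s < 0):
                raise ValueError(f"negative stability for {k}")

    def importance(self) -> dict[str, np.ndarray]:
        """I(theta_i) = F_i + S(theta_i); plain Fisher when no stability."""
        if not self.stability:
            return dict(self.fisher)
        return {k: self.fisher[k] + self.stability.get(k, 0.0)
                for k in self.fisher}

    # -- serialization -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "theta_old.npz", **self.theta_old)
        np.savez(directory / "fisher.npz", **self.fisher)
        np.savez(directory / "stability.npz", **self.stability)
        (directory / "importance_meta.json").write_text(json.dumps(
            {"lambda_reg": self.lambda_reg, "n_samples": self.n_samples}))

    @staticmethod
    def load(directory) -> "ImportanceState":
        directory = Path(directory)
        meta = json.loads((directory / "importance_meta.json").read_text())
        def _load(name):
            with np.load(directory / name) as z:
                return {k: z[k] for k in z.files}
        return ImportanceState(theta_old=_load("theta_old.npz"),
                               fisher=_load("fisher.npz"),
                               stability=_load("stability.npz"),
                               lambda_reg=meta["lambda_reg"],
                               n_samples=meta["n_samples"])


class TrajectoryBuffer:
    """Accumulates sum_t |theta_t - theta_{t-1}| per parameter during
    training; ``finalize`` divides by the step count T."""

    def __init__(self, named_params: dict[str, Parameter]):
        self._last = {k: p.data.copy() for k, p in named_params.items()
                      if not p.frozen}
        self._sum = {k: np.zeros_like(v) for k, v in self._last.items()}
        self.t = 0

    def update(self, named_params: dict[str, Parameter]) -> None:
        for k in self._sum:
            cur = named_params[k].data
            self._sum[k] += np.abs(cur - self._last[k])
            self._last[k] = cur.copy()
        self.t += 1

    def finalize(self) -> dict[str, np.ndarray]:
        if self.t == 0:
            return {k: np.zeros_like(v) for k, v in self._sum.items()}
        return {k: v / self.t for k, v in self._sum.items()}


@dataclasses.dataclass(frozen=True)
class TransitionConfig:
    mode: str = "none"            # none | ewc | vewc
    eta: float = 1e-3             # new-task learning rate
    gamma: float = 1.0            # scales the regularizer pull
    rho: float = 1e-3             # consolidated-update learning rate
    lambda_reg: float | None = None
    halved_vewc: bool = False     # use (lambda/2)(F+S) instead of lambda*I

    def validate(self) -> None:
        if self.mode not in ("none", "ewc", "vewc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.eta, self.gamma, self.rho) <= 0:
            raise ValueError("eta, gamma, rho must be > 0")

    def resolved_lambda(self) -> float:
        if self.lambda_reg is not None:
            return self.lambda_reg
        return DEFAULT_LAMBDA.get(self.mode, 0.0)


# -- Fisher estimation -----------------------------------------------------

def _log_likelihood(model, image: np.ndarray, mask: np.ndarray) -> Tensor:
    """Sum over pixels of the log-softmax probability of the true class."""
    scores = model(Tensor(image[None]))              # (1, C, H, W)
    logp = scores.log_softmax(axis=1)
    onehot = np.zeros(logp.shape)
    C = logp.shape[1]
    for c in range(C):
        onehot[0, c] = mask == c
    return (logp * Tensor(onehot)).sum()


def estimate_fisher(model: Module, samples,
                    loglik_fn=None) -> dict[str, np.ndarray]:
    """Empirical Fisher: mean over samples of squared per-sample gradients
    of the log-likelihood.  ``samples`` is a sequence of SlicePair-like
    objects with ``image`` and ``mask``; ``loglik_fn(model, sample)`` may
    replace the default per-pixel segmentation log-likelihood (e.g. for
    analytically tractable models)."""
    samples = list(samples)
    if not samples:
        raise ValueError("Fisher estimation needs at least one sample")
    params = {k: p for k, p in model.named_parameters().items()
              if not p.frozen}
    fisher = {k: np.zeros_like(p.data) for k, p in params.items()}
    for s in samples:
        model.zero_grad()
        if loglik_fn is not None:
            ll = loglik_fn(model, s)
        else:
            ll = _log_likelihood(model, s.image, s.mask)
        ll.backward()
        for k, p in params.items():
            if p.grad is not None:
                fisher[k] += p.grad ** 2
        model.zero_grad()
    n = len(samples)
    return {k: v / n for k, v in fisher.items()}


def accumulate_fisher(prior: ImportanceState,
                      new_fisher: dict[str, np.ndarray],
                      n_new: int) -> dict[str, np.ndarray]:
    """Sample-count-weighted running average of Fisher scores across
    tasks."""
    n_old = max(prior.n_samples, 0)
    total = n_old + n_new
    if total == 0:
        return dict(new_fisher)
    return {k: (prior.fisher.get(k, 0.0) * n_old + new_fisher[k] * n_new)
            / total for k in new_fisher}


# -- penalties -------------------------------------------------------------

def _quad_sum(params: dict[str, Parameter], anchors: dict[str, np.ndarray],
              weights: dict[str, np.ndarray]) -> Tensor:
    total = Tensor(0.0)
    for k, w in weights.items():
        p = params[k]
        diff = p - Tensor(anchors[k])
        total = total + (Tensor(w) * diff * diff).sum()
    return total


def ewc_penalty(params: dict[str, Parameter],
                state: ImportanceState,
                lambda_reg: float | None = None) -> Tensor:
    """(lambda/2) sum_i F_i (theta_i - theta_i_old)^2, differentiable."""
    lam = state.lambda_reg if lambda_reg is None else lambda_reg
    return _quad_sum(params, state.theta_old, state.fisher) * (lam / 2.0)


def vewc_penalty(params: dict[str, Parameter],
                 state: ImportanceState,
                 lambda_reg: float | None = None,
                 halved: bool = False) -> Tensor:
    """lambda sum_i I_i (theta - theta_old)^2 with I = F + S; ``halved``
    selects the lambda/2 variant of the same quadratic form."""
    lam = state.lambda_reg if lambda_reg is None else lambda_reg
    factor = lam / 2.0 if halved else lam
    return _quad_sum(params, state.theta_old, state.importance()) * factor


def penalty_term(model: Module, state: ImportanceState | None,
                 config: TransitionConfig) -> Tensor:
    """The active regularizer R(theta, theta_old) for one training step;
    identically zero for mode='none'."""
    config.validate()
    if config.mode == "none":
        return Tensor(0.0)
    if state is None:
        raise ValueError(f"mode={config.mode!r} requires an ImportanceState")
    params = model.named_parameters()
    lam = config.resolved_lambda()
    if config.mode == "ewc":
        pen = ewc_penalty(params, state, lambda_reg=lam)
    else:
        pen = vewc_penalty(params, state, lambda_reg=lam,
                           halved=config.halved_vewc)
    return pen * config.gamma


def penalized_step(model: Module, task_loss: Tensor,
                   state: ImportanceState | None,
                   config: TransitionConfig, optimizer) -> float:
    """One descent step on L_task + R (the active consolidation penalty).

    ``task_loss`` must be an un-backpropagated scalar Tensor built from the
    current parameters.  Returns the total loss value.  The update realizes
    theta <- theta - eta * grad(L_new) - gamma * grad(R) (descent on the
    penalized objective)."""
    total = task_loss + penalty_term(model, state, config)
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return float(total.item())
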