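"""Neural-network building blocks on top of the autodiff engine.

Modules hold named :class:`Parameter` tensors; ``named_parameters`` walks
submodules recursively producing stable dotted names ("blocks.0.attn.w_q"),
which the continual-learning state (Fisher scores, anchors, stability sums)
keys on.  Freezing is expressed through a per-parameter ``frozen`` flag that
the optimizer honours by skipping the update entirely — frozen arrays are
bitwise untouched.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "Conv2d", "DepthwiseConv2d",
    "bilinear_matrix", "bilinear_upsample2x", "Adam", "global_grad_norm",
]


class Parameter(Tensor):
    __slots__ = ("frozen",)

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.frozen = False


class Module:
    """Base class: attribute-based submodule/parameter discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                out[full] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(full))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{full}.{i}"))
                    elif isinstance(item, Parameter):
                        out[f"{full}.{i}"] = item
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def freeze(self, predicate) -> list[str]:
        """Mark parameters whose dotted name satisfies ``predicate`` frozen."""
        frozen = []
        for name, p in self.named_parameters().items():
            if predicate(name):
                p.frozen = True
                frozen.append(name)
        return frozen


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # LeCun-style small-variance init; adequate at the scales used here
    return rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalization over the trailing (embedding) dimension."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps).pow(-0.5)
        return xn * self.gamma + self.beta


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_init(rng, (out_ch, in_ch, kernel, kernel),
                                      fan_in))
        self.bias = Parameter(np.zeros(out_ch))
        self.padding = (kernel - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.weight = Parameter(_init(rng, (channels, kernel, kernel),
                                      kernel * kernel))
        self.bias = Parameter(np.zeros(channels))
        self.padding = (kernel - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias, padding=self.padding)


def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D linear-interpolation matrix (align-corners=False,
    edge-clamped), so a 2-D bilinear resize is M_h · X · M_wᵀ."""
    M = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[i, lo_c] += 1.0 - frac
        M[i, hi_c] += frac
    return M


def bilinear_upsample2x(x: Tensor) -> Tensor:
    """Bilinear ×2 on (B, C, H, W) via fixed interpolation matrices."""
    B, C, H, W = x.shape
    Mh = Tensor(bilinear_matrix(H, 2 * H))
    Mw = Tensor(bilinear_matrix(W, 2 * W))
    flat = x.reshape(B * C, H, W)
    up = (Mh @ flat) @ Mw.transpose((1, 0))
    return up.reshape(B, C, 2 * H, 2 * W)


def global_grad_norm(params) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    return float(np.sqrt(total))


class Adam:
    """Adam with optional global-norm gradient clipping; skips frozen
    parameters so their arrays stay bitwise identical."""

    def __init__(self, named_params: dict[str, Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 grad_clip_norm: float | None = None):
        self.params = dict(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip_norm = grad_clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        live = {k: p for k, p in self.params.items() if not p.frozen}
        if self.grad_clip_norm is not None:
            norm = global_grad_norm(live.values())
            if norm > self.grad_clip_norm and norm > 0:
                scale = self.grad_clip_norm / norm
                for p in live.values():
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        for k, p in live.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
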