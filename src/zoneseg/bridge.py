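"""Bridge stage: nested skip connections over encoder depths, learnable
weighted aggregation, and transformer-to-CNN feature fusion.

Each encoder block's token output, reshaped to a spatial map X^(l), feeds a
skip chain S^(l) = F_skip(X^(l)) + S^(l-1) (1x1 convolution transform;
S^(0) previous term is zero).  The chained outputs are aggregated as
S_nested = sum_i w_i S^(i) with unconstrained trainable scalars w_i
initialized to 1/n_levels.  Finally F_fusion = W_f S_nested + W_t T, where
T is the neck map and W_f, W_t are 1x1 convolutions aligning channels for
the CNN decoder.

The chain recursion uses the aggregated previous skip output S^(l-1) (the
accumulating reading); ``raw_chain=True`` switches to adding the raw
previous feature map X^(l-1) instead.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor
from ._nn import Conv2d, Module, Parameter, bilinear_matrix

__all__ = ["BridgeStage", "skip_connect", "nested_aggregate"]


def skip_connect(x_l: Tensor, s_prev: Tensor | None,
                 transform) -> Tensor:
    """S^(l) = F_skip(X^(l)) + S^(l-1); level 0 uses a zero previous term."""
    out = transform(x_l)
    if s_prev is not None:
        out = out + s_prev
    return out


def nested_aggregate(skips: list[Tensor], weights: Tensor) -> Tensor:
    """S_nested = sum_i w_i S^(i); spatially mismatched levels are bilinearly
    resampled to the finest (largest) level first."""
    if len(skips) != weights.shape[0]:
        raise ValueError("one aggregation weight per level required")
    target = max(s.shape[-1] for s in skips)
    acc = None
    for i, s in enumerate(skips):
        if s.shape[-1] != target:
            s = _resample_to(s, target)
        term = s * weights[i]
        acc = term if acc is None else acc + term
    return acc


def _resample_to(x: Tensor, size: int) -> Tensor:
    B, C, H, W = x.shape
    Mh = Tensor(bilinear_matrix(H, size))
    Mw = Tensor(bilinear_matrix(W, size))
    flat = x.reshape(B * C, H, W)
    out = (Mh @ flat) @ Mw.transpose((1, 0))
    return out.reshape(B, C, size, size)


class BridgeStage(Module):
    def __init__(self, n_levels: int, level_channels: int,
                 neck_channels: int, out_channels: int,
                 rng: np.random.Generator, raw_chain: bool = False):
        self.skip_transforms = [Conv2d(level_channels, out_channels, 1, rng)
                                for _ in range(n_levels)]
        self.agg_weights = Parameter(np.full(n_levels, 1.0 / n_levels))
        self.w_f = Conv2d(out_channels, out_channels, 1, rng)
        self.w_t = Conv2d(neck_channels, out_channels, 1, rng)
        self.raw_chain = raw_chain

    def fuse(self, s_nested: Tensor, t: Tensor) -> Tensor:
        """F_fusion = W_f S_nested + W_t T."""
        return self.w_f(s_nested) + self.w_t(t)

    def __call__(self, level_maps: list[Tensor],
                 neck_map: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (F_fusion, S_nested) given per-block spatial maps and the
        neck output T."""
        prev = None
        skips = []
        for x_l, tr in zip(level_maps, self.skip_transforms):
            s = skip_connect(x_l, prev, tr)
            skips.append(s)
            prev = s if not self.raw_chain else x_l
        s_nested = nested_aggregate(skips, self.agg_weights)
        return self.fuse(s_nested, neck_map), s_nested
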