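"""CNN decoder stage: U-Net-style reconstruction from the bridge output.

Each decoder block concatenates a skip map (the bridge's aggregated skip
output resampled to the current resolution), projects the concatenation
with a 1x1 convolution, refines with a Convolutional Bridge Layer (3x3
same-padded convolution + GELU: F_conv = GELU(W_c * X + b_c)), and doubles
the spatial resolution.  Upsampling modes:

* ``bilinear``   — fixed bilinear x2;
* ``transposed`` — zero-dilation x2 followed by a learnable 3x3 convolution
  (an exact stride-2 transposed convolution factorization);
* ``hybrid``     — bilinear x2 followed by a learnable stride-1 3x3
  convolution refinement (default; checkerboard-free).

With patch size p the decoder needs log2(p) blocks to restore the input
resolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, concatenate
from ._nn import Conv2d, Module, bilinear_matrix, bilinear_upsample2x

__all__ = ["DecoderConfig", "CBL", "Upsample2x", "DecoderStage"]


@dataclasses.dataclass(frozen=True)
class DecoderConfig:
    channels: tuple[int, ...] = (32, 16, 8)   # one entry per block
    upsample_mode: str = "hybrid"             # bilinear | transposed | hybrid
    n_classes: int = 3

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("at least one decoder block required")
        if self.upsample_mode not in ("bilinear", "transposed", "hybrid"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")


class CBL(Module):
    """Convolutional Bridge Layer: 3x3 convolution + GELU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).gelu()


class Upsample2x(Module):
    def __init__(self, channels: int, mode: str, rng: np.random.Generator):
        self.mode = mode
        if mode in ("transposed", "hybrid"):
            self.refine = Conv2d(channels, channels, 3, rng)
            if mode == "hybrid":
                # start as identity so the bilinear path dominates initially
                self.refine.weight.data[:] = 0.0
                for c in range(channels):
                    self.refine.weight.data[c, c, 1, 1] = 1.0

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "bilinear":
            return bilinear_upsample2x(x)
        if self.mode == "hybrid":
            return self.refine(bilinear_upsample2x(x))
        return self.refine(x.dilate2())


class DecoderStage(Module):
    """n blocks of (skip concat -> 1x1 projection -> CBL -> upsample x2)."""

    def __init__(self, in_channels: int, skip_channels: int,
                 config: DecoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        self.projections = []
        self.cbls = []
        self.upsamples = []
        cur = in_channels
        for ch in config.channels:
            self.projections.append(
                Conv2d(cur + skip_channels, ch, 1, rng))
            self.cbls.append(CBL(ch, ch, rng))
            self.upsamples.append(Upsample2x(ch, config.upsample_mode, rng))
            cur = ch
        self.out_channels = cur

    def __call__(self, f_fusion: Tensor, skip_source: Tensor) -> Tensor:
        x = f_fusion
        for proj, cbl, up in zip(self.projections, self.cbls,
                                 self.upsamples):
            skip = _resize(skip_source, x.shape[-1])
            x = up(cbl(proj(concatenate([x, skip], axis=1))))
        return x


def _resize(x: Tensor, size: int) -> Tensor:
    if x.shape[-1] == size:
        return x
    B, C, H, W = x.shape
    Mh = Tensor(bilinear_matrix(H, size))
    Mw = Tensor(bilinear_matrix(W, size))
    out = (Mh @ x.reshape(B * C, H, W)) @ Mw.transpose((1, 0))
    return out.reshape(B, C, size, size)
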