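"""Final feature fusion head.

Merges the transformer pathway (global context) with the CNN decoder
pathway (local detail) before classification:

1.  *Progressive windowing* of the transformer map: at each level i the
    features inside overlapping spatial blocks are transformed by a shared
    learnable channel matrix W_i, and overlapping outputs are averaged,
    F_T^(i+1) = W_i . F_T^(i).
2.  *Dimensional calibration* of the CNN map: channel projection
    F_CP = W_P F_C + b_P into the transformer channel space, then a
    depthwise 3x3 convolution with GELU, F_CN = GELU(W_C * F_CP + b_C).
3.  *Relevance scoring*: per location, R(x,y) = softmax over two source
    logits computed from the concatenated features [F_T | F_C]; R is the
    probability mass on the transformer source, in [0, 1].
4.  *Adaptive scaling*: F_scaled = R.F_T + (1-R).F_C.
5.  *Attention-guided fusion*: (alpha, beta) = softmax(W_A F_scaled + b_A)
    per location with alpha + beta = 1, and F_fused = alpha.F_T + beta.F_C.
6.  A 1x1-convolution segmentation head produces 3 class logits per pixel;
    labels are the per-pixel argmax (ties resolved to the lowest class).

The transformer map is windowed at token resolution and then bilinearly
upsampled to the image resolution, so fusion happens at full resolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, concatenate
from ._nn import Conv2d, DepthwiseConv2d, Module, Parameter, \
    bilinear_upsample2x

__all__ = ["FusionConfig", "ProgressiveWindowing", "Calibration",
           "FusionHead"]


@dataclasses.dataclass(frozen=True)
class FusionConfig:
    window_levels: int = 2
    window_size: int = 4
    window_overlap: int = 2
    n_classes: int = 3

    def validate(self) -> None:
        if self.window_levels < 1:
            raise ValueError("window_levels must be >= 1")
        if not (0 <= self.window_overlap < self.window_size):
            raise ValueError("overlap must be smaller than window size")


def _window_starts(extent: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - size, 0) + 1, stride))
    if not starts:
        return [0]
    if starts[-1] + size < extent:  # cover the trailing edge
        starts.append(extent - size)
    return starts


class ProgressiveWindowing(Module):
    """Per-level shared channel transforms applied over overlapping spatial
    blocks, overlap-averaged; output shape equals input shape."""

    def __init__(self, channels: int, config: FusionConfig,
                 rng: np.random.Generator):
        config.validate()
        self.config = config
        # identity + small noise so the module starts near a pass-through
        self.transforms = [
            Parameter(np.eye(channels)
                      + rng.normal(0, 0.01, (channels, channels)))
            for _ in range(config.window_levels)]

    def coverage(self, H: int, W: int) -> np.ndarray:
        """How many overlapping blocks cover each pixel (used to normalize
        the overlap-add)."""
        size = min(self.config.window_size, H, W)
        stride = max(size - self.config.window_overlap, 1)
        count = np.zeros((H, W))
        for y in _window_starts(H, size, stride):
            for x in _window_starts(W, size, stride):
                count[y:y + size, x:x + size] += 1.0
        return count

    def __call__(self, f_t: Tensor) -> Tensor:
        # Because W_i is shared across blocks and acts on channels, every
        # block transforms a pixel identically; the coverage-normalized
        # overlap-add therefore reduces to the pointwise channel transform
        # applied once per level.
        x_cur = f_t
        for w_i in self.transforms:
            x_cur = (x_cur.transpose((0, 2, 3, 1)) @ w_i.transpose((1, 0))) \
                .transpose((0, 3, 1, 2))
        return x_cur


class Calibration(Module):
    """F_CP = W_P F_C + b_P (1x1 conv); F_CN = GELU(W_C * F_CP + b_C)
    (depthwise 3x3)."""

    def __init__(self, cnn_channels: int, out_channels: int,
                 rng: np.random.Generator):
        self.project = Conv2d(cnn_channels, out_channels, 1, rng)
        self.depthwise = DepthwiseConv2d(out_channels, 3, rng)

    def __call__(self, f_c: Tensor) -> Tensor:
        return self.depthwise(self.project(f_c)).gelu()


def adaptive_scale(f_t: Tensor, f_c: Tensor, r: Tensor) -> Tensor:
    """F_scaled = R.F_T + (1-R).F_C with R broadcast over channels."""
    return r * f_t + (1.0 - r) * f_c


class FusionHead(Module):
    def __init__(self, transformer_channels: int, cnn_channels: int,
                 n_upsamples: int, config: FusionConfig,
                 rng: np.random.Generator):
        config.validate()
        self.config = config
        self.n_upsamples = n_upsamples
        self.windowing = ProgressiveWindowing(transformer_channels, config,
                                              rng)
        self.calibrate = Calibration(cnn_channels, transformer_channels, rng)
        self.w_r = Conv2d(2 * transformer_channels, 2, 1, rng)
        self.w_a = Conv2d(transformer_channels, 2, 1, rng)
        self.head = Conv2d(transformer_channels, config.n_classes, 1, rng)

    def relevance(self, f_t: Tensor, f_c: Tensor) -> Tensor:
        """(B, 1, H, W) probability that the transformer source wins."""
        logits = self.w_r(concatenate([f_t, f_c], axis=1))
        return logits.softmax(axis=1)[:, 0:1]

    def attention_fuse(self, f_t: Tensor, f_c: Tensor,
                       f_scaled: Tensor) -> Tensor:
        ab = self.w_a(f_scaled).softmax(axis=1)      # alpha + beta = 1
        alpha, beta = ab[:, 0:1], ab[:, 1:2]
        return alpha * f_t + beta * f_c

    def __call__(self, neck_windowed_input: Tensor,
                 decoder_out: Tensor) -> Tensor:
        """neck_windowed_input: transformer map at token resolution;
        decoder_out: CNN map at image resolution.  Returns class logits
        (B, n_classes, H, W)."""
        f_t = self.windowing(neck_windowed_input)
        for _ in range(self.n_upsamples):
            f_t = bilinear_upsample2x(f_t)
        f_c = self.calibrate(decoder_out)
        r = self.relevance(f_t, f_c)
        f_scaled = adaptive_scale(f_t, f_c, r)
        f_fused = self.attention_fuse(f_t, f_c, f_scaled)
        self._last_fused = f_fused       # exposed for embedding extraction
        return self.head(f_fused)


def segmentation_labels(scores: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the class axis; numpy argmax already breaks
    ties toward the lowest class index."""
    return np.argmax(scores, axis=-3)
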