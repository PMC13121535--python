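"""Transformer encoder stage: patch tokenization, learnable positional
encoding, multi-head self-attention blocks with post-norm residuals, a neck
projection to spatial feature maps, and the pretrained-weight blend/freeze
policy.

An input slice of size H x W is cut into non-overlapping p x p patches,
each flattened and linearly projected to a D-dimensional token; a learnable
positional matrix P is added.  Each block computes

    Z'  = Norm(Z  + MSA(Z))
    Z'' = Norm(Z' + MLP(Z'))

with MSA the standard scaled dot-product attention softmax(QK^T/sqrt(d_k))V
per head and MLP two linear layers around a GELU.  Normalization is applied
*after* the residual sum (post-norm), matching the governing equations.
Blocks may attend globally or within a local spatial window (additive mask).

The neck projects tokens to ``neck_dim`` channels, layer-normalizes, and
reshapes them to a sqrt(N) x sqrt(N) spatial map for the bridge stage.

When a pretrained checkpoint is available its weights can be blended into
the trainable initialization as theta' = lambda*theta_pre +
(1-lambda)*theta_train; the attention blocks and neck can additionally be
frozen so fine-tuning never moves them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, concatenate
from ._nn import LayerNorm, Linear, Module, Parameter

__all__ = ["EncoderConfig", "TransformerEncoder", "patchify",
           "blend_pretrained", "local_attention_mask"]


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    input_size: int = 64          # H = W of the input slice
    patch_size: int = 8
    embed_dim: int = 64
    n_heads: int = 4
    n_blocks: int = 2
    neck_dim: int = 16
    mlp_ratio: int = 4
    lambda_blend: float = 1.0
    freeze_vit_and_neck: bool = False
    attention_kinds: tuple[str, ...] | None = None  # per block: global|local
    local_window: int = 4         # token-grid window for local attention

    def validate(self) -> None:
        if self.input_size % self.patch_size:
            raise ValueError("input_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not (0.0 <= self.lambda_blend <= 1.0):
            raise ValueError("lambda_blend must lie in [0, 1]")
        if self.attention_kinds is not None and \
                len(self.attention_kinds) != self.n_blocks:
            raise ValueError("attention_kinds must have one entry per block")

    @property
    def n_tokens(self) -> int:
        return (self.input_size // self.patch_size) ** 2

    @property
    def token_grid(self) -> int:
        return self.input_size // self.patch_size


def patchify(image: Tensor, patch_size: int) -> Tensor:
    """(B, H, W) -> (B, N, p*p) of row-major flattened non-overlapping
    patches, scanned row-major over the patch grid."""
    B, H, W = image.shape
    p = patch_size
    if H % p or W % p:
        raise ValueError(f"image size {H}x{W} not divisible by patch {p}")
    x = image.reshape(B, H // p, p, W // p, p)
    x = x.transpose((0, 1, 3, 2, 4))          # (B, gh, gw, p, p)
    return x.reshape(B, (H // p) * (W // p), p * p)


def local_attention_mask(grid: int, window: int) -> np.ndarray:
    """Additive (0 / -inf) mask restricting attention to tokens whose
    patch-grid coordinates fall in the same window x window tile."""
    idx = np.arange(grid * grid)
    r, c = idx // grid, idx % grid
    tile = (r // window) * ((grid + window - 1) // window) + (c // window)
    allowed = tile[:, None] == tile[None, :]
    mask = np.where(allowed, 0.0, -1e30)
    return mask


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_k = dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def __call__(self, z: Tensor, mask: np.ndarray | None = None,
                 return_weights: bool = False):
        B, N, D = z.shape
        h, dk = self.n_heads, self.d_k

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, N, h, dk).transpose((0, 2, 1, 3))

        q, k, v = split(self.w_q(z)), split(self.w_k(z)), split(self.w_v(z))
        logits = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
        if mask is not None:
            logits = logits + Tensor(mask)
        attn = logits.softmax(axis=-1)            # (B, h, N, N)
        out = attn @ v                            # (B, h, N, dk)
        out = out.transpose((0, 2, 1, 3)).reshape(B, N, D)
        out = self.w_o(out)
        if return_weights:
            return out, attn
        return out


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).gelu())


class TransformerBlock(Module):
    """Post-norm block: Z' = Norm(Z + MSA(Z)); Z'' = Norm(Z' + MLP(Z'))."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator,
                 mask: np.ndarray | None = None):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.mlp = MLP(dim, dim * mlp_ratio, rng)
        self.norm2 = LayerNorm(dim)
        self._mask = mask

    def __call__(self, z: Tensor) -> Tensor:
        z1 = self.norm1(z + self.attn(z, mask=self._mask))
        return self.norm2(z1 + self.mlp(z1))


class TransformerEncoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        c = config
        self.w_e = Linear(c.patch_size ** 2, c.embed_dim, rng)
        self.pos = Parameter(
            rng.normal(0.0, 0.02, size=(c.n_tokens, c.embed_dim)))
        kinds = c.attention_kinds or ("global",) * c.n_blocks
        self.blocks = [
            TransformerBlock(
                c.embed_dim, c.n_heads, c.mlp_ratio, rng,
                mask=(local_attention_mask(c.token_grid, c.local_window)
                      if kind == "local" else None))
            for kind in kinds]
        self.neck_proj = Linear(c.embed_dim, c.neck_dim, rng)
        self.neck_norm = LayerNorm(c.neck_dim)
        if c.freeze_vit_and_neck:
            self.apply_freeze_policy()

    # -- forward -----------------------------------------------------------
    def embed(self, tokens: Tensor) -> Tensor:
        return self.w_e(tokens) + self.pos

    def __call__(self, image: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns (neck spatial map (B, neck_dim, g, g), per-block token
        outputs) where g = input_size / patch_size."""
        c = self.config
        z = self.embed(patchify(image, c.patch_size))
        block_outputs = []
        for blk in self.blocks:
            z = blk(z)
            block_outputs.append(z)
        z_neck = self.neck_norm(self.neck_proj(z))     # (B, N, neck_dim)
        g = c.token_grid
        B = image.shape[0]
        neck_map = z_neck.transpose((0, 2, 1)).reshape(B, c.neck_dim, g, g)
        return neck_map, block_outputs

    # -- pretrained-weight policy -------------------------------------------
    def apply_freeze_policy(self) -> list[str]:
        """Freeze attention blocks and neck (the generically pretrained
        parts); patch embedding and positional encoding stay trainable."""
        return self.freeze(lambda name: name.startswith(("blocks.",
                                                         "neck_")))

    def tokens_to_map(self, z: Tensor) -> Tensor:
        """Reshape (B, N, D) tokens to a (B, D, g, g) spatial map with
        token i at row-major spatial index i."""
        B, N, D = z.shape
        g = self.config.token_grid
        return z.transpose((0, 2, 1)).reshape(B, D, g, g)


def blend_pretrained(theta_pre: dict[str, np.ndarray],
                     theta_train: dict[str, np.ndarray],
                     lambda_blend: float) -> dict[str, np.ndarray]:
    """theta' = lambda*theta_pre + (1-lambda)*theta_train, elementwise, for
    every key present in the pretrained checkpoint."""
    if not (0.0 <= lambda_blend <= 1.0):
        raise ValueError("lambda_blend must lie in [0, 1]")
    out = dict(theta_train)
    for k, pre in theta_pre.items():
        if k not in theta_train:
            raise KeyError(f"pretrained key {k!r} absent from model")
        if np.shape(pre) != np.shape(theta_train[k]):
            raise ValueError(f"shape mismatch for {k!r}")
        out[k] = lambda_blend * np.asarray(pre) \
            + (1.0 - lambda_blend) * np.asarray(theta_train[k])
    return out
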