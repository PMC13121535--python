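"""End-to-end hybrid transformer-CNN segmentation network.

Pipeline per 2-D slice: transformer encoder (patch tokens, self-attention,
neck) -> bridge (nested skips + fusion) -> CNN decoder (CBL + x2
upsampling) -> final feature fusion -> 3-class segmentation head.  Input is
a (B, H, W) batch of grayscale slices scaled to [0, 1] internally; output
is a (B, 3, H, W) logit map over background / transition zone / peripheral
zone.

``ModelConfig.desk()`` is the tiny CPU-trainable configuration used
throughout the tests and benchmarks; ``ModelConfig.paper_scale()`` mirrors
a ViT-B-style encoder and exists for completeness (it is far too large to
train here).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor
from ._nn import Module
from .bridge import BridgeStage
from .decoder import DecoderConfig, DecoderStage
from .encoder import EncoderConfig, TransformerEncoder, blend_pretrained
from .fusion import FusionConfig, FusionHead, segmentation_labels

__all__ = ["ModelConfig", "ZoneSegNet", "segmentation_labels"]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    decoder: DecoderConfig = dataclasses.field(default_factory=DecoderConfig)
    fusion: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    seed: int = 0

    @staticmethod
    def desk(input_size: int = 64, seed: int = 0,
             freeze: bool = False) -> "ModelConfig":
        """Tiny CPU-scale model: p=8, D=64, 2 blocks, 4 heads."""
        import math
        n_up = int(math.log2(8))
        channels = (32, 16, 8)[:n_up]
        return ModelConfig(
            encoder=EncoderConfig(input_size=input_size, patch_size=8,
                                  embed_dim=64, n_heads=4, n_blocks=2,
                                  neck_dim=16,
                                  freeze_vit_and_neck=freeze),
            decoder=DecoderConfig(channels=channels),
            fusion=FusionConfig(),
            seed=seed)

    @staticmethod
    def micro(input_size: int = 32, seed: int = 0,
              freeze: bool = False) -> "ModelConfig":
        """Smallest useful model; used by the multi-seed benchmarks."""
        return ModelConfig(
            encoder=EncoderConfig(input_size=input_size, patch_size=8,
                                  embed_dim=32, n_heads=2, n_blocks=2,
                                  neck_dim=12, mlp_ratio=2,
                                  freeze_vit_and_neck=freeze),
            decoder=DecoderConfig(channels=(16, 12, 8)),
            fusion=FusionConfig(),
            seed=seed)

    @staticmethod
    def paper_scale(seed: int = 0) -> "ModelConfig":
        """ViT-B-like encoder on 128x128 slices with four decoder blocks."""
        return ModelConfig(
            encoder=EncoderConfig(input_size=128, patch_size=16,
                                  embed_dim=768, n_heads=12, n_blocks=12,
                                  neck_dim=256, freeze_vit_and_neck=True),
            decoder=DecoderConfig(channels=(256, 128, 64, 32)),
            fusion=FusionConfig(),
            seed=seed)


class ZoneSegNet(Module):
    def __init__(self, config: ModelConfig):
        import math
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc = config.encoder
        n_up = int(math.log2(enc.patch_size))
        if len(config.decoder.channels) != n_up:
            raise ValueError(
                f"decoder needs log2(patch_size)={n_up} blocks to restore "
                f"full resolution, got {len(config.decoder.channels)}")
        self.encoder = TransformerEncoder(enc, rng)
        dec0 = config.decoder.channels[0]
        self.bridge = BridgeStage(n_levels=enc.n_blocks,
                                  level_channels=enc.embed_dim,
                                  neck_channels=enc.neck_dim,
                                  out_channels=dec0, rng=rng)
        self.decoder = DecoderStage(in_channels=dec0, skip_channels=dec0,
                                    config=config.decoder, rng=rng)
        self.fusion = FusionHead(transformer_channels=enc.neck_dim,
                                 cnn_channels=self.decoder.out_channels,
                                 n_upsamples=n_up, config=config.fusion,
                                 rng=rng)

    def __call__(self, images: Tensor | np.ndarray) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        x = x * (1.0 / 255.0)          # slices arrive on the 0-255 scale
        neck_map, block_tokens = self.encoder(x)
        level_maps = [self.encoder.tokens_to_map(z) for z in block_tokens]
        f_fusion, s_nested = self.bridge(level_maps, neck_map)
        dec_out = self.decoder(f_fusion, skip_source=s_nested)
        return self.fusion(neck_map, dec_out)

    # -- inference helpers -------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self(Tensor(images)).softmax(axis=1).numpy()

    def predict(self, images: np.ndarray) -> np.ndarray:
        return segmentation_labels(self(Tensor(images)).numpy())

    def fused_features(self, images: np.ndarray) -> np.ndarray:
        """Final fused feature map (B, C, H, W) from the last forward."""
        self(Tensor(images))
        return self.fusion._last_fused.numpy()

    # -- pretrained policy -------------------------------------------------
    def load_pretrained_encoder(self, checkpoint: dict[str, np.ndarray],
                                lambda_blend: float | None = None) -> None:
        """Blend a pretrained encoder checkpoint into the current encoder
        weights at initialization time: theta' = lambda*theta_pre +
        (1-lambda)*theta_train."""
        lam = (self.config.encoder.lambda_blend
               if lambda_blend is None else lambda_blend)
        current = {k: v.data for k, v in
                   self.encoder.named_parameters().items()}
        blended = blend_pretrained(checkpoint, current, lam)
        self.encoder.load_state_dict(
            {k: blended.get(k, v) for k, v in current.items()})
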