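"""Bridge, decoder and final-fusion stages: governing-equation examples,
per-pixel projection oracles, shape contracts and differentiability."""

import numpy as np
import pytest

from zoneseg._autograd import Tensor
from zoneseg._nn import Conv2d
from zoneseg.bridge import BridgeStage, nested_aggregate, skip_connect
from zoneseg.decoder import CBL, DecoderConfig, DecoderStage, Upsample2x
from zoneseg.fusion import (Calibration, FusionConfig, FusionHead,
                            ProgressiveWindowing, adaptive_scale,
                            segmentation_labels)
from zoneseg.model import ModelConfig, ZoneSegNet


def _gelu(x):
    from scipy.special import erf
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


class TestBridge:
    def test_skip_identity_and_zero_transforms(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 4, 4)))
        s_prev = Tensor(rng.normal(size=(1, 2, 4, 4)))
        assert np.allclose(skip_connect(x, None, lambda t: t).numpy(),
                           x.numpy())
        out = skip_connect(x, s_prev, lambda t: t * 0.0)
        assert np.allclose(out.numpy(), s_prev.numpy())

    def test_three_identity_levels_telescope(self, rng):
        xs = [Tensor(rng.normal(size=(1, 2, 4, 4))) for _ in range(3)]
        s = None
        for x in xs:
            s = skip_connect(x, s, lambda t: t)
        assert np.allclose(s.numpy(), sum(x.numpy() for x in xs))

    def test_nested_aggregate_examples(self, rng):
        maps = [Tensor(np.ones((1, 1, 4, 4))),
                Tensor(np.full((1, 1, 4, 4), 3.0))]
        out = nested_aggregate(maps, Tensor(np.array([0.2, 0.8])))
        assert np.allclose(out.numpy(), 2.6)
        one_hot = nested_aggregate(maps, Tensor(np.array([0.0, 1.0])))
        assert np.allclose(one_hot.numpy(), 3.0)
        zero = nested_aggregate(maps, Tensor(np.zeros(2)))
        assert np.allclose(zero.numpy(), 0.0)

    def test_fuse_projection_matches_per_pixel_oracle(self, rng):
        br = BridgeStage(n_levels=2, level_channels=3, neck_channels=2,
                         out_channels=4, rng=rng)
        s = rng.normal(size=(1, 4, 5, 5))
        t = rng.normal(size=(1, 2, 5, 5))
        out = br.fuse(Tensor(s), Tensor(t)).numpy()
        wf = br.w_f.weight.data[:, :, 0, 0]
        wt = br.w_t.weight.data[:, :, 0, 0]
        ref = np.zeros_like(out)
        for i in range(5):
            for j in range(5):
                ref[0, :, i, j] = wf @ s[0, :, i, j] + br.w_f.bias.data \
                    + wt @ t[0, :, i, j] + br.w_t.bias.data
        assert np.allclose(out, ref, atol=1e-6)

    def test_fuse_endpoint_identities(self, rng):
        br = BridgeStage(n_levels=1, level_channels=2, neck_channels=2,
                         out_channels=2, rng=rng)
        for conv in (br.w_f, br.w_t):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        br.w_f.weight.data[:, :, 0, 0] = np.eye(2)
        s = Tensor(rng.normal(size=(1, 2, 4, 4)))
        t = Tensor(rng.normal(size=(1, 2, 4, 4)))
        assert np.allclose(br.fuse(s, t).numpy(), s.numpy())
        br.w_f.weight.data[:] = 0
        br.w_t.weight.data[:, :, 0, 0] = np.eye(2)
        assert np.allclose(br.fuse(s, t).numpy(), t.numpy())

    def test_fusion_linearity(self, rng):
        br = BridgeStage(n_levels=1, level_channels=2, neck_channels=2,
                         out_channels=3, rng=rng)
        br.w_f.bias.data[:] = 0
        br.w_t.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        y = Tensor(rng.normal(size=(1, 3, 4, 4)))
        t = Tensor(rng.normal(size=(1, 2, 4, 4)))
        zero = Tensor(np.zeros((1, 3, 4, 4)))
        zero_t = Tensor(np.zeros((1, 2, 4, 4)))
        lhs = br.fuse(x * 2.0 + y * 3.0, t).numpy()
        rhs = 2.0 * br.fuse(x, zero_t).numpy() \
            + 3.0 * br.fuse(y, zero_t).numpy() + br.fuse(zero, t).numpy()
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_gradient_reaches_every_aggregation_weight(self, rng):
        br = BridgeStage(n_levels=3, level_channels=2, neck_channels=2,
                         out_channels=2, rng=rng)
        maps = [Tensor(rng.normal(size=(1, 2, 4, 4))) for _ in range(3)]
        neck = Tensor(rng.normal(size=(1, 2, 4, 4)))
        out, _ = br(maps, neck)
        (out * out).sum().backward()
        assert br.agg_weights.grad is not None
        assert np.all(np.abs(br.agg_weights.grad) > 0)


class TestDecoder:
    def test_cbl_delta_kernel_is_gelu(self, rng):
        cbl = CBL(2, 2, rng)
        cbl.conv.weight.data[:] = 0
        for c in range(2):
            cbl.conv.weight.data[c, c, 1, 1] = 1.0
        cbl.conv.bias.data[:] = 0
        x = rng.normal(size=(1, 2, 5, 5))
        assert np.allclose(cbl(Tensor(x)).numpy(), _gelu(x), atol=1e-10)

    def test_cbl_zero_input_zero_bias_gives_zero(self, rng):
        cbl = CBL(2, 3, rng)
        cbl.conv.bias.data[:] = 0
        out = cbl(Tensor(np.zeros((1, 2, 5, 5)))).numpy()
        assert np.allclose(out, 0.0)

    def test_conv_matches_sliding_window_oracle(self, rng):
        conv = Conv2d(1, 1, 3, rng)
        x = rng.normal(size=(1, 1, 5, 5))
        out = conv(Tensor(x)).numpy()
        k = conv.weight.data[0, 0]
        xp = np.pad(x[0, 0], 1)
        ref = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                ref[i, j] = (xp[i:i + 3, j:j + 3] * k).sum() \
                    + conv.bias.data[0]
        assert np.allclose(out[0, 0], ref, atol=1e-10)

    def test_translation_covariance_on_interior(self, rng):
        conv = Conv2d(1, 1, 3, rng)
        x = rng.normal(size=(1, 1, 8, 8))
        shifted = np.roll(x, 1, axis=3)
        out = conv(Tensor(x)).numpy()
        out_s = conv(Tensor(shifted)).numpy()
        assert np.allclose(out_s[..., 2:-2, 2:-2],
                           np.roll(out, 1, axis=3)[..., 2:-2, 2:-2],
                           atol=1e-10)

    @pytest.mark.parametrize("mode", ["bilinear", "transposed", "hybrid"])
    def test_upsample_doubles_spatial_dims(self, mode, rng):
        up = Upsample2x(3, mode, rng)
        out = up(Tensor(rng.normal(size=(2, 3, 8, 8))))
        assert out.shape == (2, 3, 16, 16)

    def test_bilinear_mode_preserves_constant(self, rng):
        up = Upsample2x(1, "bilinear", rng)
        out = up(Tensor(np.full((1, 1, 4, 4), 2.5))).numpy()
        assert np.allclose(out, 2.5)

    def test_decoder_restores_full_resolution(self, rng):
        cfg = DecoderConfig(channels=(8, 8, 4, 4))
        dec = DecoderStage(in_channels=6, skip_channels=6, config=cfg,
                           rng=rng)
        x = Tensor(rng.normal(size=(1, 6, 8, 8)))
        out = dec(x, skip_source=x)
        assert out.shape == (1, 4, 128, 128)    # 8 * 2**4

    def test_gradient_reaches_skip_input(self, rng):
        cfg = DecoderConfig(channels=(4, 4))
        dec = DecoderStage(in_channels=2, skip_channels=2, config=cfg,
                           rng=rng)
        x = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        skip = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        (dec(x, skip) ** 2.0).sum().backward()
        assert skip.grad is not None and np.abs(skip.grad).max() > 0
        assert x.grad is not None and np.abs(x.grad).max() > 0


class TestFusion:
    def test_windowing_identity_zero_and_scalar_composition(self, rng):
        cfg = FusionConfig(window_levels=2)
        pw = ProgressiveWindowing(3, cfg, rng)
        x = Tensor(rng.normal(size=(1, 3, 8, 8)))
        for t in pw.transforms:
            t.data = np.eye(3)
        assert np.allclose(pw(x).numpy(), x.numpy())
        pw.transforms[0].data = np.eye(3) * 2.0
        pw.transforms[1].data = np.eye(3) * 3.0
        assert np.allclose(pw(x).numpy(), 6.0 * x.numpy())
        pw.transforms[1].data = np.zeros((3, 3))
        assert np.allclose(pw(x).numpy(), 0.0)

    def test_window_coverage_counts_overlap(self, rng):
        pw = ProgressiveWindowing(2, FusionConfig(window_size=4,
                                                  window_overlap=2), rng)
        cov = pw.coverage(8, 8)
        assert cov.min() >= 1
        assert cov.max() > 1          # overlapping blocks double-cover

    def test_calibration_delta_kernel_is_gelu_of_projection(self, rng):
        cal = Calibration(2, 2, rng)
        cal.project.weight.data[:] = 0
        cal.project.weight.data[:, :, 0, 0] = np.eye(2)
        cal.project.bias.data[:] = 0
        cal.depthwise.weight.data[:] = 0
        cal.depthwise.weight.data[:, 1, 1] = 1.0
        cal.depthwise.bias.data[:] = 0
        x = rng.normal(size=(1, 2, 5, 5))
        assert np.allclose(cal(Tensor(x)).numpy(), _gelu(x), atol=1e-10)

    def test_calibration_zero_input_zero_bias(self, rng):
        cal = Calibration(3, 4, rng)
        cal.project.bias.data[:] = 0
        cal.depthwise.bias.data[:] = 0
        out = cal(Tensor(np.zeros((1, 3, 4, 4)))).numpy()
        assert np.allclose(out, 0.0)

    def test_depthwise_matches_per_channel_oracle(self, rng):
        cal = Calibration(2, 2, rng)
        x = rng.normal(size=(1, 2, 5, 5))
        proj = cal.project(Tensor(x))
        out = cal.depthwise(proj).numpy()
        ref = np.zeros_like(out)
        for c in range(2):
            xp = np.pad(proj.numpy()[0, c], 1)
            for i in range(5):
                for j in range(5):
                    ref[0, c, i, j] = (xp[i:i + 3, j:j + 3]
                                       * cal.depthwise.weight.data[c]).sum() \
                        + cal.depthwise.bias.data[c]
        assert np.allclose(out, ref, atol=1e-6)

    def _head(self, rng, C=3):
        return FusionHead(transformer_channels=C, cnn_channels=C,
                          n_upsamples=0, config=FusionConfig(), rng=rng)

    def test_relevance_symmetric_and_saturated(self, rng):
        head = self._head(rng)
        head.w_r.weight.data[:] = 0
        head.w_r.bias.data[:] = 0
        f = Tensor(rng.normal(size=(1, 3, 4, 4)))
        r = head.relevance(f, f).numpy()
        assert np.allclose(r, 0.5)
        head.w_r.bias.data[:] = [10.0, -10.0]
        assert np.allclose(head.relevance(f, f).numpy(), 1.0, atol=1e-4)
        head.w_r.bias.data[:] = [1.0, 0.0]
        e = np.e
        assert np.allclose(head.relevance(f, f).numpy(), e / (e + 1.0),
                           atol=1e-10)

    def test_adaptive_scale_endpoints_and_midpoint(self):
        f_t = Tensor(np.full((1, 2, 3, 3), 2.0))
        f_c = Tensor(np.full((1, 2, 3, 3), 4.0))
        one = Tensor(np.ones((1, 1, 3, 3)))
        assert np.allclose(adaptive_scale(f_t, f_c, one).numpy(), 2.0)
        assert np.allclose(adaptive_scale(f_t, f_c, one * 0.0).numpy(), 4.0)
        assert np.allclose(adaptive_scale(f_t, f_c, one * 0.5).numpy(), 3.0)

    def test_attention_fuse_weights_sum_to_one(self, rng):
        head = self._head(rng)
        f_t = Tensor(rng.normal(size=(1, 3, 4, 4)))
        f_c = Tensor(rng.normal(size=(1, 3, 4, 4)))
        ab = head.w_a(f_t).softmax(axis=1).numpy()
        assert np.allclose(ab.sum(axis=1), 1.0, atol=1e-6)
        # equal sources pass through regardless of weights
        head.w_a.weight.data[:] = 0
        head.w_a.bias.data[:] = 0
        out = head.attention_fuse(f_t, f_t, f_c).numpy()
        assert np.allclose(out, f_t.numpy(), atol=1e-12)

    def test_attention_fuse_saturates_to_transformer_source(self, rng):
        head = self._head(rng)
        head.w_a.weight.data[:] = 0
        head.w_a.bias.data[:] = [15.0, -15.0]
        f_t = Tensor(rng.normal(size=(1, 3, 4, 4)))
        f_c = Tensor(rng.normal(size=(1, 3, 4, 4)))
        out = head.attention_fuse(f_t, f_c, f_c).numpy()
        assert np.allclose(out, f_t.numpy(), atol=1e-4)

    def test_segmentation_head_probabilities_and_ties(self, rng):
        head = self._head(rng)
        scores = head.head(Tensor(rng.normal(size=(2, 3, 4, 4))))
        probs = scores.softmax(axis=1).numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        labels = segmentation_labels(scores.numpy())
        assert set(np.unique(labels)) <= {0, 1, 2}
        uniform = np.zeros((1, 3, 2, 2))
        assert np.all(segmentation_labels(uniform) == 0)  # lowest index


class TestEndToEnd:
    def test_forward_contract_on_128_slice(self, rng):
        model = ZoneSegNet(ModelConfig.desk(128, seed=0))
        out = model(Tensor(rng.random((1, 128, 128)) * 255.0))
        assert out.shape == (1, 3, 128, 128)

    def test_forward_is_deterministic(self, micro_model, rng):
        x = rng.random((1, 32, 32)) * 255.0
        a = micro_model(Tensor(x)).numpy()
        b = micro_model(Tensor(x)).numpy()
        assert np.array_equal(a, b)

    def test_finite_difference_gradient_through_fusion(self, rng):
        """End-to-end differentiability of the fusion operators on a tiny
        instance, checked against central differences at 1e-4."""
        head = FusionHead(transformer_channels=2, cnn_channels=2,
                          n_upsamples=0, config=FusionConfig(), rng=rng)
        f_t = rng.normal(size=(1, 2, 3, 3))
        f_c = rng.normal(size=(1, 2, 3, 3))

        def forward(ft_arr):
            return float((head(Tensor(ft_arr), Tensor(f_c)) ** 2.0)
                         .sum().item())

        t = Tensor(f_t, requires_grad=True)
        (head(t, Tensor(f_c)) ** 2.0).sum().backward()
        eps = 1e-6
        num = np.zeros_like(f_t)
        it = np.nditer(f_t, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            up, dn = f_t.copy(), f_t.copy()
            up[idx] += eps
            dn[idx] -= eps
            num[idx] = (forward(up) - forward(dn)) / (2 * eps)
            it.iternext()
        assert np.allclose(t.grad, num, atol=1e-4)
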