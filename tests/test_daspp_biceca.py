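"""Decode-head checks: pyramid branches, channel attention, head contract."""

import numpy as np
import pytest

from plaquenet import autograd as ag
from plaquenet.autograd import Tensor
from plaquenet.config import DASPPConfig, miniature_run_config
from plaquenet.daspp_biceca import BICECA, DASPP, adaptive_lcci_kernel_size
from plaquenet.exceptions import ConfigurationError
from plaquenet.model import build_model

import oracles


def daspp_cfg(rates=(1, 2, 4), channels=8, pool=False):
    return DASPPConfig(atrous_rates=rates, branch_channels=channels,
                       include_image_pool=pool, low_level_proj_channels=4,
                       refine_channels=8)


class TestDASPP:
    def test_single_rate_identity_kernels_reduce_to_fused_projection(self, rng):
        cfg = daspp_cfg(rates=(1,), channels=3)
        daspp = DASPP(3, cfg, norm="none", rng=rng)
        branch = daspp.branch_r1
        branch.depthwise.weight.data[:] = 0.0
        branch.depthwise.weight.data[:, 0, 1, 1] = 1.0
        branch.pointwise.weight.data = np.eye(3)[:, :, None, None].astype(float)
        x = np.abs(rng.normal(size=(1, 3, 8, 8)))  # nonnegative input
        out = daspp(Tensor(x)).data
        fused = np.maximum(
            np.einsum("oc,nchw->nohw", daspp.fuse.weight.data[:, :, 0, 0], x), 0
        )
        assert np.abs(out - fused).max() < 1e-10

    def test_constant_input_gives_spatially_constant_interior(self, rng):
        # zero "same" padding makes borders deviate; the interior (beyond
        # the largest dilated kernel extent, 4 px here) must be constant
        cfg = daspp_cfg(pool=True)
        daspp = DASPP(4, cfg, norm="bn", rng=rng)
        out = daspp(Tensor(np.full((2, 4, 12, 12), 0.7))).data
        interior = out[:, :, 4:-4, 4:-4]
        assert np.abs(interior - interior[:, :, :1, :1]).max() < 1e-9

    def test_matches_branchwise_loop_oracle(self, rng):
        cfg = daspp_cfg(rates=(1, 2, 4), channels=4)
        daspp = DASPP(4, cfg, norm="none", rng=rng)
        x = rng.normal(size=(1, 4, 16, 16))
        out = daspp(Tensor(x)).data
        branch_outs = []
        for r in (1, 2, 4):
            branch = getattr(daspp, f"branch_r{r}")
            dw = np.zeros_like(x)
            for c in range(4):
                dw[:, c:c + 1] = oracles.conv2d_loops(
                    x[:, c:c + 1], branch.depthwise.weight.data[c:c + 1],
                    dilation=r,
                )
            pw = oracles.pointwise_conv_loops(
                dw, branch.pointwise.weight.data[:, :, 0, 0])
            branch_outs.append(np.maximum(pw, 0))
        cat = np.concatenate(branch_outs, axis=1)
        ref = np.maximum(oracles.pointwise_conv_loops(
            cat, daspp.fuse.weight.data[:, :, 0, 0]), 0)
        assert np.abs(out - ref).max() < 1e-5

    def test_strictly_increasing_rates_required(self):
        with pytest.raises(ConfigurationError):
            DASPPConfig(atrous_rates=(4, 2, 1))
        with pytest.raises(ConfigurationError):
            DASPPConfig(atrous_rates=())


class TestBICECA:
    def test_attention_factors_strictly_inside_unit_interval(self, rng):
        # scales kept below the float64 saturation point of the sigmoid;
        # mathematically φ ∈ (0,1) for every finite input
        att = BICECA(8, 3, rng=rng)
        for scale in (0.1, 1.0, 3.0):
            x = Tensor(rng.normal(size=(2, 8, 4, 4)) * scale)
            s = att.dsconv_pointwise(att.dsconv_depthwise(x))
            phi = att.attention_factors(s).data
            assert (phi > 1e-12).all() and (phi < 1 - 1e-12).all()

    def test_zero_input_chain_gives_exactly_half_gates(self, rng):
        att = BICECA(8, 3, rng=rng)
        x = Tensor(np.zeros((1, 8, 4, 4)))
        s = att.dsconv_pointwise(att.dsconv_depthwise(x))
        assert (s.data == 0).all()  # bias-free separable conv
        phi = att.attention_factors(s).data
        assert (phi == 0.5).all()
        assert (att(x).data == 0).all()

    def test_output_bounded_by_twice_shared_features(self, rng):
        att = BICECA(8, 3, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 5, 5)))
        s = att.dsconv_pointwise(att.dsconv_depthwise(x)).data
        out = att(x).data
        assert (out >= 0).all()
        assert (out <= 2 * np.abs(s) + 1e-12).all()

    def test_matches_stepwise_oracle(self, rng):
        att = BICECA(8, 3, rng=rng)
        x = rng.normal(size=(1, 8, 4, 4))
        out = att(Tensor(x)).data
        # oracle: depthwise+pointwise loops, GAP, circular 1D conv, sigmoid
        s = np.zeros_like(x)
        for c in range(8):
            s[:, c:c + 1] = oracles.conv2d_loops(
                x[:, c:c + 1], att.dsconv_depthwise.weight.data[c:c + 1])
        s = oracles.pointwise_conv_loops(
            s, att.dsconv_pointwise.weight.data[:, :, 0, 0])
        q = np.maximum(s.mean(axis=(2, 3)), 0.0)[0]
        w = att.lcci_weight.data
        lcci = np.array([
            sum(w[j] * q[(c + j - 1) % 8] for j in range(3)) for c in range(8)
        ])
        phi = 1 / (1 + np.exp(-lcci))
        ref = np.maximum(phi[None, :, None, None] * s + s, 0.0)
        assert np.abs(out - ref).max() < 1e-5

    def test_saturated_lcci_drives_gates_to_one(self, rng):
        att = BICECA(8, 3, rng=rng)
        att.lcci_weight.data = np.full(3, 1e4)
        x = Tensor(np.abs(rng.normal(size=(1, 8, 4, 4))) + 0.5)
        s = att.dsconv_pointwise(att.dsconv_depthwise(x))
        q = np.maximum(s.data.mean(axis=(2, 3)), 0)
        assert q.sum() > 0  # positive descriptor somewhere
        phi = att.attention_factors(s).data
        positive = np.array([
            sum(q[0, (c + j - 1) % 8] for j in range(3)) for c in range(8)
        ]) > 1e-4
        assert (phi[0, positive] > 1 - 1e-12).all()
        out = att(x).data
        ref = np.maximum(2 * s.data, 0)
        assert np.abs(out - ref)[:, positive].max() < 1e-8

    def test_channels_below_kernel_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            BICECA(2, 3, rng=rng)

    def test_adaptive_kernel_rule_is_odd(self):
        for c in (8, 16, 64, 256, 512):
            k = adaptive_lcci_kernel_size(c)
            assert k % 2 == 1 and k >= 1


class TestDecodeHead:
    def test_logits_shape_and_determinism(self, rng):
        cfg = miniature_run_config(seed=5)
        outs = []
        for _ in range(2):
            model = build_model(cfg)
            model.eval()
            x = np.random.default_rng(9).normal(size=(1, 1, 64, 64))
            outs.append(model.forward_logits(x)[0].data)
        assert outs[0].shape == (1, 2, 64, 64)
        assert (outs[0] == outs[1]).all()

    def test_perturbation_stays_within_receptive_field(self, rng):
        cfg = miniature_run_config(seed=2)
        cfg.head.include_image_pool = False  # global pool has global reach
        model = build_model(cfg)
        model.eval()
        x = np.random.default_rng(4).normal(size=(1, 1, 192, 192))
        base = model.forward_logits(x)[0].data
        x2 = x.copy()
        ci = cj = 96
        x2[0, 0, ci, cj] += 10.0
        diff = np.abs(model.forward_logits(x2)[0].data - base)[0].max(axis=0)
        changed = np.argwhere(diff > 1e-12)
        assert changed.size > 0
        # conservative analytic radius of the composed operators, in input px
        radius = 0
        radius += 1 + 2                      # stem convs (stride 1 then 2)
        radius += 3 * 4 * 2                  # stage-1 convs/pool at stride 4
        radius += 3 * 4 * 2                  # stage-2 stride-2 convs
        radius += (2 * 4 + 1) * 8            # atrous rate-4 depthwise at stride 8
        radius += 8 + 8                      # BICECA depthwise conv
        radius += 2 * 8                      # bicubic ×2 (4-tap support)
        radius += 4 + 4                      # refinement conv at stride 4
        radius += 2 * 4                      # final bicubic ×4
        cheb = np.abs(changed - [ci, cj]).max()
        assert cheb <= radius

    def test_translation_covariance_on_interior(self, rng):
        """The convolution/resampling path is covariant to shifts that are
        multiples of the total stride.  The channel-attention gates are a
        global statistic (they see the rolled borders), so they are frozen
        at their zero-descriptor value of 0.5 for this check."""
        cfg = miniature_run_config(seed=3)
        cfg.head.include_image_pool = False
        model = build_model(cfg)
        model.eval()
        att = model.head.biceca
        att.attention_factors = lambda s: Tensor(
            np.full(s.data.shape[:2], 0.5))
        stride = cfg.backbone.total_stride
        base_img = np.random.default_rng(11).normal(size=(1, 1, 256, 256))
        shifted = np.roll(base_img, (stride, stride), axis=(2, 3))
        out = model.forward_logits(base_img)[0].data
        out_shift = model.forward_logits(shifted)[0].data
        rolled = np.roll(out, (stride, stride), axis=(2, 3))
        m = 96  # clear of the rolled band plus the receptive-field radius
        diff = np.abs(out_shift - rolled)[:, :, m:-m, m:-m]
        assert diff.max() < 1e-6
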