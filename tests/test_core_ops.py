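"""Operator-level checks against brute-force nested-loop oracles."""

import numpy as np
import pytest

from plaquenet import core_ops as co
from plaquenet.exceptions import ConfigurationError, ShapeError

import oracles


def rand_map(rng, n=1, c=3, h=8, w=8):
    return rng.normal(size=(n, c, h, w))


# ---------------------------------------------------------------------
# atrous convolution
# ---------------------------------------------------------------------

class TestAtrousConv:
    def test_rate_one_equals_standard_conv(self, rng):
        x = rand_map(rng, 1, 3, 8, 8)
        w = rng.normal(size=(2, 3, 3, 3))
        got = co.atrous_conv(x, w, rate=1)
        ref = oracles.conv2d_loops(x, w)
        assert np.abs(got - ref).max() < 1e-6

    def test_impulse_spreads_by_rate(self, rng):
        x = np.zeros((1, 1, 9, 9))
        x[0, 0, 4, 4] = 1.0
        w = rng.normal(size=(1, 1, 3, 3))
        out = co.atrous_conv(x, w, rate=2)
        nz = np.argwhere(out[0, 0] != 0)
        assert set(map(tuple, nz)) <= {
            (4 + 2 * di, 4 + 2 * dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
        }
        # cross-correlation with an impulse reproduces the flipped kernel
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                assert out[0, 0, 4 + 2 * di, 4 + 2 * dj] == pytest.approx(
                    w[0, 0, 1 - di, 1 - dj]
                )

    def test_constant_input_interior_response(self, rng):
        w = rng.normal(size=(1, 2, 3, 3))
        x = np.full((1, 2, 9, 9), 1.7)
        out = co.atrous_conv(x, w, rate=2)
        assert out[0, 0, 3:-3, 3:-3] == pytest.approx(1.7 * w.sum(), abs=1e-9)

    @pytest.mark.parametrize("rate", [0, -1])
    def test_nonpositive_rate_rejected(self, rate, rng):
        with pytest.raises(ConfigurationError):
            co.atrous_conv(rand_map(rng), rng.normal(size=(1, 3, 3, 3)), rate=rate)

    def test_kernel_exceeding_padded_input_rejected(self, rng):
        # effective extent 3·(2−1)+1 = 4 > 1 + 2·(3·1//2) = 3 padded pixels
        with pytest.raises(ShapeError):
            co.atrous_conv(
                rand_map(rng, 1, 1, 1, 1), rng.normal(size=(1, 1, 2, 2)), rate=3
            )

    @pytest.mark.parametrize("rate", [1, 2, 3])
    def test_matches_loop_oracle(self, rng, rate):
        for _ in range(5):
            x = rand_map(rng, 1, 2, 9, 9)
            w = rng.normal(size=(2, 2, 3, 3))
            b = rng.normal(size=2)
            got = co.atrous_conv(x, w, b, rate=rate)
            ref = oracles.conv2d_loops(x, w, b, dilation=rate)
            assert np.abs(got - ref).max() < 1e-5


# ---------------------------------------------------------------------
# depthwise / pointwise / separable
# ---------------------------------------------------------------------

class TestDepthwiseConv:
    def test_delta_kernel_is_identity(self, rng):
        x = rand_map(rng, 2, 3, 6, 6)
        w = np.zeros((3, 1, 3, 3))
        w[:, 0, 1, 1] = 1.0
        assert np.abs(co.depthwise_conv(x, w) - x).max() < 1e-12

    def test_matches_per_channel_loop_oracle(self, rng):
        x = rand_map(rng, 1, 2, 6, 6)
        w = rng.normal(size=(2, 1, 3, 3))
        got = co.depthwise_conv(x, w)
        ref = oracles.depthwise_conv_loops(x, w)
        assert np.abs(got - ref).max() < 1e-6

    def test_channel_independence_under_swap(self, rng):
        x = rand_map(rng, 1, 2, 6, 6)
        w = rng.normal(size=(2, 1, 3, 3))
        out = co.depthwise_conv(x, w)
        out_sw = co.depthwise_conv(x[:, ::-1], w[::-1])
        assert np.abs(out_sw - out[:, ::-1]).max() < 1e-12

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            co.depthwise_conv(rand_map(rng, 1, 3), rng.normal(size=(2, 1, 3, 3)))


class TestPointwiseConv:
    def test_identity_mixing(self, rng):
        x = rand_map(rng, 1, 3, 5, 5)
        assert np.abs(co.pointwise_conv(x, np.eye(3)) - x).max() < 1e-12

    def test_channel_sum(self, rng):
        x = rand_map(rng, 1, 2, 5, 5)
        out = co.pointwise_conv(x, np.ones((1, 2)))
        assert np.abs(out[:, 0] - x.sum(axis=1)).max() < 1e-12

    def test_matches_per_pixel_matvec_oracle(self, rng):
        x = rand_map(rng, 1, 4, 5, 5)
        w = rng.normal(size=(3, 4))
        got = co.pointwise_conv(x, w)
        ref = oracles.pointwise_conv_loops(x, w)
        assert np.abs(got - ref).max() < 1e-6

    def test_spatial_extent_above_one_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            co.pointwise_conv(rand_map(rng), rng.normal(size=(2, 3, 3, 3)))


class TestDepthwiseSeparable:
    def test_identity_composition(self, rng):
        x = rand_map(rng, 1, 3, 6, 6)
        wd = np.zeros((3, 1, 3, 3))
        wd[:, 0, 1, 1] = 1.0
        out = co.depthwise_separable_conv(x, wd, np.eye(3))
        assert np.abs(out - x).max() < 1e-12

    def test_equals_dense_conv_with_outer_product_kernel(self, rng):
        x = rand_map(rng, 1, 3, 7, 7)
        wd = rng.normal(size=(3, 1, 3, 3))
        wp = rng.normal(size=(2, 3))
        got = co.depthwise_separable_conv(x, wd, wp)
        w_full = np.einsum("oc,cuv->ocuv", wp, wd[:, 0])
        ref = oracles.conv2d_loops(x, w_full)
        assert np.abs(got - ref).max() < 1e-5

    def test_parameter_count_strictly_smaller(self):
        kh = kw = 3
        for c, o in [(4, 8), (16, 32), (2, 2)]:
            assert kh * kw * c + c * o < kh * kw * c * o


# ---------------------------------------------------------------------
# bicubic upsampling
# ---------------------------------------------------------------------

class TestBicubicUpsample:
    def test_partition_of_unity(self, rng):
        w = co.cubic_interp_weights(rng.random(1000))
        assert np.abs(w.sum(axis=-1) - 1).max() < 1e-9

    def test_interpolating_kernel_at_integer_offsets(self):
        assert co.cubic_kernel(0.0) == pytest.approx(1.0)
        for t in (-2, -1, 1, 2):
            assert co.cubic_kernel(float(t)) == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", [0.5, 1.5, 2, 3])
    def test_constant_preserved_at_any_scale(self, scale):
        x = np.full((1, 2, 6, 6), 2.45)
        out = co.bicubic_upsample(x, scale)
        assert np.abs(out - 2.45).max() < 1e-12

    def test_scale_one_is_identity(self, rng):
        x = rand_map(rng, 1, 2, 6, 6)
        assert np.abs(co.bicubic_upsample(x, 1) - x).max() < 1e-12

    def test_linear_ramp_reproduced_in_interior(self):
        x = np.fromfunction(lambda n, c, y, xx: 2 * xx + 3 * y, (1, 1, 8, 8))
        out = co.bicubic_upsample(x, 2)
        src = (np.arange(16) + 0.5) / 2 - 0.5
        expect = 2 * src[None, :] + 3 * src[:, None]
        assert np.abs(out[0, 0, 3:-3, 3:-3] - expect[3:-3, 3:-3]).max() < 1e-6

    @pytest.mark.parametrize("scale", [1.5, 2])
    def test_matches_16_tap_oracle(self, rng, scale):
        x = rand_map(rng, 1, 2, 6, 6)
        got = co.bicubic_upsample(x, scale)
        ref = oracles.bicubic_upsample_loops(x, scale)
        assert np.abs(got - ref).max() < 1e-5

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            co.bicubic_upsample(rand_map(rng), 0)


# ---------------------------------------------------------------------
# reflect conv stack + bilinear upsample
# ---------------------------------------------------------------------

class TestReflectConvStack:
    def test_single_delta_kernel_is_identity(self, rng):
        x = rand_map(rng, 1, 1, 6, 6)
        k = np.zeros((1, 1, 3, 3))
        k[0, 0, 1, 1] = 1.0
        assert np.abs(co.reflect_conv_stack(x, [k]) - x).max() < 1e-12

    def test_constant_has_no_border_attenuation(self, rng):
        k = rng.normal(size=(1, 1, 3, 3))
        out = co.reflect_conv_stack(np.full((1, 1, 6, 6), 2.0), [k])
        assert np.abs(out - 2.0 * k.sum()).max() < 1e-9

    def test_two_layer_stack_matches_composed_oracle(self, rng):
        x = rand_map(rng, 1, 1, 6, 6)
        k1 = rng.normal(size=(1, 1, 3, 3))
        k2 = rng.normal(size=(1, 1, 3, 3))
        got = co.reflect_conv_stack(x, [k1, k2])
        ref = oracles.reflect_conv_loops(oracles.reflect_conv_loops(x, k1), k2)
        assert np.abs(got - ref).max() < 1e-6

    def test_padding_wider_than_input_rejected(self, rng):
        with pytest.raises(ShapeError):
            co.reflect_conv_stack(rand_map(rng, 1, 1, 2, 2), [np.ones((1, 1, 7, 7))])


class TestBilinearReflectUpsample:
    def test_corner_weights_partition_of_unity(self, rng):
        ax, ay = rng.random(1000), rng.random(1000)
        w = co.bilinear_corner_weights(ax, ay)
        assert (w >= 0).all()
        assert np.abs(w.sum(axis=-1) - 1).max() < 1e-12

    def test_zero_offsets_give_nearest_copy(self, rng):
        x = rand_map(rng, 1, 2, 6, 6)
        out = co.bilinear_reflect_upsample(
            x, 2, alpha_x=np.zeros(12), alpha_y=np.zeros(12), apply_avg=False
        )
        src = np.clip(
            np.floor((np.arange(12) + 0.5) / 2 - 0.5).astype(int), 0, 5
        )
        assert np.abs(out - x[:, :, src[:, None], src[None, :]]).max() < 1e-12

    def test_constant_preserved(self):
        out = co.bilinear_reflect_upsample(np.full((1, 1, 5, 5), 1.3), 2)
        assert np.abs(out - 1.3).max() < 1e-12

    def test_matches_blend_plus_mean_oracle(self, rng):
        x = rand_map(rng, 1, 1, 5, 5)
        got = co.bilinear_reflect_upsample(x, 2)
        ref = oracles.bilinear_upsample_loops(x, 2)
        assert np.abs(got - ref).max() < 1e-6


# ---------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------

OPS = {
    "atrous": lambda x, rng: co.atrous_conv(x, rng.normal(size=(2, x.shape[1], 3, 3)), rate=2),
    "depthwise": lambda x, rng: co.depthwise_conv(x, rng.normal(size=(x.shape[1], 1, 3, 3))),
    "pointwise": lambda x, rng: co.pointwise_conv(x, rng.normal(size=(2, x.shape[1]))),
    "separable": lambda x, rng: co.depthwise_separable_conv(
        x, rng.normal(size=(x.shape[1], 1, 3, 3)), rng.normal(size=(2, x.shape[1]))
    ),
    "reflect_stack": lambda x, rng: co.reflect_conv_stack(
        x, [rng.normal(size=(x.shape[1], x.shape[1], 3, 3))]
    ),
}


@pytest.mark.parametrize("name", sorted(OPS))
def test_linearity_of_convolution_operators(name, rng):
    op = OPS[name]
    for _ in range(3):
        x = rand_map(rng, 1, 3, 7, 7)
        y = rand_map(rng, 1, 3, 7, 7)
        op_rng = np.random.default_rng(7)
        lhs = op(2.0 * x + 0.5 * y, op_rng)
        op_rng = np.random.default_rng(7)
        a = op(x, op_rng)
        op_rng = np.random.default_rng(7)
        b = op(y, op_rng)
        assert np.abs(lhs - (2.0 * a + 0.5 * b)).max() < 1e-5


@pytest.mark.parametrize("scale", [2, 3])
def test_integer_scale_shape_contract(rng, scale):
    x = rand_map(rng, 1, 1, 6, 5)
    assert co.bicubic_upsample(x, scale).shape == (1, 1, 6 * scale, 5 * scale)
    assert co.bilinear_reflect_upsample(x, scale).shape == (1, 1, 6 * scale, 5 * scale)


def test_same_padding_preserves_spatial_dims(rng):
    x = rand_map(rng, 1, 2, 7, 9)
    assert co.atrous_conv(x, rng.normal(size=(2, 2, 3, 3)), rate=3).shape[2:] == (7, 9)
    assert co.depthwise_conv(x, rng.normal(size=(2, 1, 5, 5))).shape[2:] == (7, 9)
    assert co.reflect_conv_stack(x, [rng.normal(size=(2, 2, 3, 3))]).shape[2:] == (7, 9)


def test_all_operators_finite_on_finite_input(rng):
    x = rand_map(rng, 1, 3, 8, 8) * 1e3
    for name, op in OPS.items():
        assert np.isfinite(op(x, rng)).all(), name
    assert np.isfinite(co.bicubic_upsample(x, 2)).all()
    assert np.isfinite(co.bilinear_reflect_upsample(x, 2)).all()
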