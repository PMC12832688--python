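"""Contracts of the pure-numeric building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

from pneunet.blocks import (
    ASPPConfig,
    ASPPWeights,
    ConvSpec,
    LearnablePoolingConfig,
    LearnablePoolWeights,
    SEConfig,
    SEWeights,
    aspp,
    atrous_conv_1d,
    conv2d,
    gap_pool,
    learnable_pool,
    se_block,
    se_squeeze,
    separable_conv_cost,
    standard_conv_cost,
)


class TestConvCosts:
    @pytest.mark.parametrize("k,cin,cout,expected", [
        (3, 3, 32, 864),
        (1, 128, 32, 4096),
        (3, 128, 32, 36864),
    ])
    def test_standard_cost(self, k, cin, cout, expected):
        assert standard_conv_cost(ConvSpec(k, cin, cout)) == expected

    @pytest.mark.parametrize("k,cin,cout,expected", [
        (3, 128, 32, 5248),
        (3, 32, 32, 1312),
    ])
    def test_separable_cost(self, k, cin, cout, expected):
        assert separable_conv_cost(ConvSpec(k, cin, cout)) == expected

    def test_cost_ratio_identity(self):
        """separable/standard = 1/C_out + 1/k^2."""
        spec = ConvSpec(3, 128, 32)
        ratio = separable_conv_cost(spec) / standard_conv_cost(spec)
        assert ratio == pytest.approx(1 / 32 + 1 / 9)
        assert ratio == pytest.approx(5248 / 36864)

    def test_standard_cost_rejects_depthwise(self):
        with pytest.raises(ValueError):
            standard_conv_cost(ConvSpec(3, 16, 16, depthwise=True))

    @given(k=st.integers(2, 7), cin=st.integers(1, 64), cout=st.integers(2, 64))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_separable_always_cheaper(self, k, cin, cout):
        spec = ConvSpec(k, cin, cout)
        assert separable_conv_cost(spec) < standard_conv_cost(spec)


class TestAtrousConv1D:
    def test_rate_one(self):
        assert atrous_conv_1d([1, 2, 3, 4, 5], [1, 1, 1], 1).tolist() == [6, 9, 12]

    def test_rate_two_single_position(self):
        assert atrous_conv_1d([1, 2, 3, 4, 5], [1, 1, 1], 2).tolist() == [9]

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=20), st.integers(1, 2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_identity_kernel(self, xs, rate):
        y = atrous_conv_1d(xs, [1, 0, 0], rate)
        np.testing.assert_allclose(y, xs[: len(y)])

    def test_signal_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            atrous_conv_1d([1, 2, 3], [1, 1, 1], 2)  # span 5 > 3


class TestSESqueeze:
    def test_constant_map(self):
        fm = np.full((5, 7, 3), 2.25)
        np.testing.assert_allclose(se_squeeze(fm), [2.25, 2.25, 2.25])

    def test_single_channel_mean(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert se_squeeze(fm)[0] == pytest.approx(2.5)

    def test_zero_map(self):
        np.testing.assert_array_equal(se_squeeze(np.zeros((3, 3, 4))), np.zeros(4))


def _random_se_weights(rng, c, u):
    return SEWeights(w1=rng.normal(size=(c, u)), b1=rng.normal(size=u),
                     w2=rng.normal(size=(u, c)), b2=rng.normal(size=c))


class TestSEBlock:
    def test_zero_weights_halve_input(self):
        cfg = SEConfig(channels=8, squeeze_units=2)
        w = SEWeights(np.zeros((8, 2)), np.zeros(2), np.zeros((2, 8)), np.zeros(8))
        fm = np.random.default_rng(0).random((4, 4, 8))
        np.testing.assert_allclose(se_block(fm, cfg, w), 0.5 * fm)

    def test_zero_input_stays_zero(self):
        cfg = SEConfig(channels=8, squeeze_units=2)
        w = _random_se_weights(np.random.default_rng(1), 8, 2)
        out = se_block(np.zeros((3, 3, 8)), cfg, w)
        np.testing.assert_array_equal(out, np.zeros((3, 3, 8)))

    def test_matches_longhand_chain(self):
        """Gates equal a hand-rolled squeeze -> affine -> rectify -> affine
        -> sigmoid computation with the same weights."""
        rng = np.random.default_rng(2)
        cfg = SEConfig(channels=8, squeeze_units=3)
        w = _random_se_weights(rng, 8, 3)
        fm = rng.normal(size=(4, 4, 8))
        s = np.array([fm[:, :, c].sum() / 16 for c in range(8)])
        h = np.maximum(s @ w.w1 + w.b1, 0)
        g = 1 / (1 + np.exp(-(h @ w.w2 + w.b2)))
        np.testing.assert_allclose(se_block(fm, cfg, w), fm * g, atol=1e-12)
        assert np.all((g > 0) & (g < 1))

    def test_channel_mismatch_raises(self):
        cfg = SEConfig(channels=8, squeeze_units=2)
        w = _random_se_weights(np.random.default_rng(0), 8, 2)
        with pytest.raises(ValueError, match="channels"):
            se_block(np.zeros((2, 2, 4)), cfg, w)


def _dilate_kernel(kern: np.ndarray, rate: int) -> np.ndarray:
    """Insert rate-1 zero rows/columns between the taps of a 2-D kernel."""
    k = kern.shape[0]
    span = (k - 1) * rate + 1
    out = np.zeros((span, span))
    out[::rate, ::rate] = kern
    return out


class TestASPP:
    def _cfg_weights(self, rng, cin=8, bc=4):
        cfg = ASPPConfig(in_channels=cin, branch_channels=bc, fuse_channels=cin)
        kernels = [rng.normal(size=(1, 1, cin, bc))]
        biases = [rng.normal(size=bc)]
        for _ in cfg.dilation_rates:
            kernels.append(rng.normal(size=(3, 3, cin, bc)))
            biases.append(rng.normal(size=bc))
        w = ASPPWeights(kernels, biases,
                        fuse_kernel=rng.normal(size=(1, 1, cfg.concat_channels, cin)),
                        fuse_bias=rng.normal(size=cin))
        return cfg, w

    def test_spatial_dims_preserved(self):
        rng = np.random.default_rng(0)
        cfg, w = self._cfg_weights(rng)
        for shape in [(9, 9), (12, 17), (5, 5)]:
            out = aspp(rng.normal(size=shape + (8,)), cfg, w)
            assert out.shape == shape + (8,)

    def test_zero_kernels_give_constant_bias(self):
        rng = np.random.default_rng(1)
        cfg, w = self._cfg_weights(rng)
        for kern in w.branch_kernels:
            kern[...] = 0.0
        for b in w.branch_biases:
            b[...] = 0.0
        w.fuse_kernel[...] = 0.0
        out = aspp(rng.normal(size=(6, 6, 8)), cfg, w)
        np.testing.assert_allclose(out, np.broadcast_to(w.fuse_bias, (6, 6, 8)))

    @pytest.mark.parametrize("rate", [1, 3, 6])
    def test_dilated_equals_zero_inserted_dense(self, rate):
        """A dilated 3x3 convolution equals dense convolution with the
        kernel expanded by inserting rate-1 zero rows/columns."""
        rng = np.random.default_rng(rate)
        x = rng.normal(size=(9, 9, 1))
        kern = rng.normal(size=(3, 3, 1, 1))
        got = conv2d(x, kern, stride=1, dilation=rate, padding="same")
        expected = correlate2d(x[:, :, 0], _dilate_kernel(kern[:, :, 0, 0], rate),
                               mode="same", boundary="fill")
        np.testing.assert_allclose(got[:, :, 0], expected, atol=1e-6)

    def test_dilated_2d_matches_1d_oracle_separably(self):
        """A separable (outer-product) dilated 2-D kernel factorizes into two
        1-D dilated passes, each checked against the 1-D oracle."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(11, 11))
        wr = rng.normal(size=3)
        wc = rng.normal(size=3)
        rate = 3
        kern = np.einsum("i,j->ij", wr, wc)[:, :, None, None]
        got = conv2d(x[:, :, None], kern, dilation=rate, padding="valid")[:, :, 0]
        rows = np.stack([atrous_conv_1d(row, wc, rate) for row in x])
        expected = np.stack([atrous_conv_1d(col, wr, rate) for col in rows.T]).T
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_channel_mismatch_raises(self):
        rng = np.random.default_rng(0)
        cfg, w = self._cfg_weights(rng)
        with pytest.raises(ValueError, match="channels"):
            aspp(np.zeros((4, 4, 5)), cfg, w)


class TestLearnablePool:
    def _zero_weights(self, cin=6, hidden=4):
        return LearnablePoolWeights(
            w_hidden=np.zeros((1, 1, cin, hidden)), b_hidden=np.zeros(hidden),
            w_score=np.zeros((1, 1, hidden, 1)), b_score=np.zeros(1))

    def test_zero_weights_half_spatial_sum(self):
        cfg = LearnablePoolingConfig(in_channels=6, hidden_channels=4)
        fm = np.random.default_rng(0).random((5, 3, 6))
        res = learnable_pool(fm, cfg, self._zero_weights())
        np.testing.assert_allclose(res.attention_map, 0.5)
        np.testing.assert_allclose(res.pooled, 0.5 * fm.sum(axis=(0, 1)))

    def test_single_position(self):
        cfg = LearnablePoolingConfig(in_channels=6, hidden_channels=4)
        rng = np.random.default_rng(1)
        fm = rng.normal(size=(1, 1, 6))
        w = self._zero_weights()
        w.b_score[...] = 0.7
        res = learnable_pool(fm, cfg, w)
        a = 1 / (1 + np.exp(-0.7))
        np.testing.assert_allclose(res.pooled, fm[0, 0] * a)

    def test_unit_map_two_by_two(self):
        cfg = LearnablePoolingConfig(in_channels=6, hidden_channels=4)
        res = learnable_pool(np.ones((2, 2, 6)), cfg, self._zero_weights())
        np.testing.assert_allclose(res.pooled, np.full(6, 2.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_attention_strictly_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        cfg = LearnablePoolingConfig(in_channels=3, hidden_channels=2)
        w = LearnablePoolWeights(rng.normal(size=(1, 1, 3, 2)), rng.normal(size=2),
                                 rng.normal(size=(1, 1, 2, 1)), rng.normal(size=1))
        res = learnable_pool(rng.normal(size=(4, 4, 3)), cfg, w)
        assert np.all(res.attention_map > 0) and np.all(res.attention_map < 1)
        assert res.pooled.shape == (3,)


class TestGapPool:
    def test_constant(self):
        np.testing.assert_allclose(gap_pool(np.full((3, 3, 2), 4.5)), [4.5, 4.5])

    def test_equals_se_squeeze(self):
        fm = np.random.default_rng(0).normal(size=(6, 5, 4))
        np.testing.assert_array_equal(gap_pool(fm), se_squeeze(fm))

    def test_hand_mean(self):
        fm = np.array([[0.0, 2.0], [4.0, 6.0]])[:, :, None]
        assert gap_pool(fm)[0] == pytest.approx(3.0)


class TestSpecValidation:
    def test_depthwise_requires_equal_channels(self):
        with pytest.raises(ValueError):
            ConvSpec(3, 8, 16, depthwise=True)

    def test_dilation_rates_must_increase(self):
        with pytest.raises(ValueError):
            ASPPConfig(dilation_rates=(3, 1, 6))

    def test_squeeze_units_below_channels(self):
        with pytest.raises(ValueError):
            SEConfig(channels=8, squeeze_units=8)
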