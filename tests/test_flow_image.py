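"""Multiscale Glow flows: bijectivity, log-determinants, bases."""

import numpy as np
import pytest

from mvflow._autodiff import Tensor
from mvflow.flow_image import (
    ChannelwiseBase,
    Invertible1x1ConvLU,
    MultiscaleLatent,
    base_log_prob,
    build_image_flow,
    decode,
    encode,
    init_actnorm,
    invertible_conv_logdet,
)


@pytest.fixture
def tiny_flow(rng):
    m = build_image_flow((1, 16, 16), levels=2, steps_per_level=4,
                         hidden_channels=16, seed=0)
    init_actnorm(m, rng.standard_normal((16, 1, 16, 16)))
    for p in m.parameters():
        p.data += 0.02 * rng.standard_normal(p.data.shape)
    return m


def test_dimension_bookkeeping_across_squeeze_and_split():
    m = build_image_flow((1, 16, 16), levels=2, steps_per_level=1, hidden_channels=8)
    # squeeze makes 4x8x8; level-1 split exits 2x8x8; level 2 exits 8x4x4
    assert m.latent_shapes == [(2, 8, 8), (8, 4, 4)]
    assert m.total_latent_dim == 256  # bijection preserves dimension


@pytest.mark.parametrize(
    "shape,levels,steps,hc",
    [
        ((1, 40, 40, 64), 3, 32, 128),   # volumetric two-view MTL configuration
        ((1, 96, 128), 5, 12, 256),      # 2D slice configuration
        ((1, 16, 16, 16), 2, [2, 3], 8),  # per-level step list, shallow -> deep
    ],
)
def test_standard_configurations_build(shape, levels, steps, hc):
    m = build_image_flow(shape, levels, steps, hc)
    assert m.total_latent_dim == int(np.prod(shape))
    if isinstance(steps, list):
        assert m.steps == steps


def test_indivisible_spatial_size_rejected():
    with pytest.raises(ValueError, match="divisible"):
        build_image_flow((1, 12, 16), levels=3, steps_per_level=1, hidden_channels=8)


def test_encode_decode_round_trip(tiny_flow, rng):
    x = rng.standard_normal((32, 1, 16, 16))
    lat, _ = encode(tiny_flow, x)
    back = decode(tiny_flow, lat)
    assert np.max(np.abs(back - x)) <= 1e-4
    # dimension conserved across blocks
    assert lat.total_dim == 256


def test_encode_is_deterministic(tiny_flow, rng):
    x = rng.standard_normal((2, 1, 16, 16))
    l1, d1 = encode(tiny_flow, x)
    l2, d2 = encode(tiny_flow, x)
    for a, b in zip(l1.blocks, l2.blocks):
        assert np.array_equal(a, b)
    assert np.array_equal(d1, d2)


def test_encode_requires_initialized_actnorm(rng):
    m = build_image_flow((1, 8, 8), 1, 1, 8)
    with pytest.raises(RuntimeError, match="not initialized"):
        encode(m, rng.standard_normal((2, 1, 8, 8)))


def test_logdet_matches_numerical_jacobian_on_toy(rng):
    m = build_image_flow((1, 4, 4), levels=1, steps_per_level=1, hidden_channels=8,
                         seed=1)
    init_actnorm(m, rng.standard_normal((8, 1, 4, 4)))
    for p in m.parameters():
        p.data += 0.05 * rng.standard_normal(p.data.shape)
    x0 = rng.standard_normal((1, 1, 4, 4))
    _, ld = encode(m, x0)
    d = 16
    J = np.zeros((d, d))
    eps = 1e-6
    for i in range(d):
        xp, xm = x0.ravel().copy(), x0.ravel().copy()
        xp[i] += eps
        xm[i] -= eps
        zp = encode(m, xp.reshape(1, 1, 4, 4))[0].flatten()[0]
        zm = encode(m, xm.reshape(1, 1, 4, 4))[0].flatten()[0]
        J[:, i] = (zp - zm) / (2 * eps)
    assert abs(ld[0] - np.linalg.slogdet(J)[1]) <= 1e-2


class TestActNorm:
    def test_post_init_channel_statistics(self, rng):
        m = build_image_flow((1, 8, 8), 1, 2, 8, seed=0)
        x = rng.standard_normal((16, 1, 8, 8)) * 3 + 5
        init_actnorm(m, x)
        an = m.level_steps[0][0].actnorm
        from mvflow.flow_image import _squeeze

        y, _ = an.forward(_squeeze(Tensor(x), 2))
        means = y.data.mean(axis=(0, 2, 3))
        sds = y.data.std(axis=(0, 2, 3))
        assert np.all(np.abs(means) <= 1e-4)
        assert np.allclose(sds, 1.0, atol=1e-6)

    def test_double_initialization_rejected(self, rng):
        m = build_image_flow((1, 8, 8), 1, 1, 8)
        x = rng.standard_normal((8, 1, 8, 8))
        init_actnorm(m, x)
        with pytest.raises(RuntimeError, match="already"):
            init_actnorm(m, x)

    def test_single_sample_warmup_rejected(self, rng):
        m = build_image_flow((1, 8, 8), 1, 1, 8)
        with pytest.raises(ValueError):
            init_actnorm(m, rng.standard_normal((1, 1, 8, 8)))

    def test_constant_channel_gets_sd_floor(self):
        m = build_image_flow((1, 8, 8), 1, 1, 8)
        init_actnorm(m, np.full((8, 1, 8, 8), 3.0))
        an = m.level_steps[0][0].actnorm
        assert np.all(np.isfinite(an.log_scale.data))  # no division by zero


class TestInvertibleConv:
    def test_identity_weights_give_zero_logdet(self):
        P, L, U = np.eye(3), np.eye(3), np.eye(3)
        assert invertible_conv_logdet((P, L, U), (8, 8)) == 0.0

    def test_scaled_identity_closed_form(self):
        P, L, U = np.eye(3), np.eye(3), 2.0 * np.eye(3)
        assert invertible_conv_logdet((P, L, U), (8, 8)) == pytest.approx(64 * 3 * np.log(2))

    def test_lu_logdet_matches_dense_determinant(self):
        conv = Invertible1x1ConvLU(4, 2, np.random.default_rng(7))
        conv.log_s.data += 0.3
        dense = np.linalg.slogdet(conv.weight_np())[1]
        assert abs(invertible_conv_logdet(conv, (5, 5)) - 25 * dense) <= 1e-8

    def test_zero_diagonal_rejected(self):
        U = np.eye(3)
        U[1, 1] = 0.0
        with pytest.raises(ValueError, match="singular"):
            invertible_conv_logdet((np.eye(3), np.eye(3), U), (4, 4))


class TestChannelwiseBase:
    def test_parameter_count_is_2c_regardless_of_resolution(self):
        small = ChannelwiseBase(3, (4, 4))
        big = ChannelwiseBase(3, (64, 64, 64))
        count = lambda b: sum(p.data.size for p in b.parameters())
        assert count(small) == count(big) == 6

    def test_log_prob_at_mode_of_standard_base(self):
        b = ChannelwiseBase(2, (4, 4))
        d = 32
        lp = base_log_prob(b, np.zeros((1, 2, 4, 4)))
        assert lp[0] == pytest.approx(-(d / 2) * np.log(2 * np.pi))

    def test_log_scale_shift_lowers_density_by_known_amount(self):
        b = ChannelwiseBase(2, (4, 4))
        lp0 = base_log_prob(b, np.zeros((1, 2, 4, 4)))[0]
        b.s.data[:] = np.log(2.0)
        lp1 = base_log_prob(b, np.zeros((1, 2, 4, 4)))[0]
        assert lp0 - lp1 == pytest.approx(16 * 2 * np.log(2))

    def test_expected_log_prob_of_standard_normal_samples(self, rng):
        b = ChannelwiseBase(1, (8, 8))
        z = rng.standard_normal((1000, 1, 8, 8))
        d = 64
        expected = -(d / 2) * (np.log(2 * np.pi) + 1)
        assert base_log_prob(b, z).mean() == pytest.approx(expected, rel=0.05)

    def test_log_scales_clamped(self):
        b = ChannelwiseBase(2, (4, 4))
        b.s.data[:] = 100.0
        base_log_prob(b, np.zeros((1, 2, 4, 4)))
        assert np.all(np.abs(b.s.data) <= 5.0)

    def test_shape_mismatch_rejected(self):
        b = ChannelwiseBase(2, (4, 4))
        with pytest.raises(ValueError):
            base_log_prob(b, np.zeros((1, 2, 8, 8)))


def test_decode_of_zero_latent_is_finite(tiny_flow):
    zero = MultiscaleLatent([np.zeros((1,) + s) for s in tiny_flow.latent_shapes])
    img = decode(tiny_flow, zero)
    assert img.shape == (1, 1, 16, 16)
    assert np.all(np.isfinite(img))


def test_decode_is_continuous_in_latent_scale(tiny_flow, rng):
    lat, _ = encode(tiny_flow, rng.standard_normal((1, 1, 16, 16)))
    flat = lat.flatten()
    out1 = decode(tiny_flow, MultiscaleLatent.unflatten(flat, tiny_flow.latent_shapes))
    out2 = decode(tiny_flow, MultiscaleLatent.unflatten(flat * (1 + 1e-3),
                                                        tiny_flow.latent_shapes))
    assert np.max(np.abs(out2 - out1)) <= 0.1 * (np.max(np.abs(out1)) + 1.0)


def test_latent_shape_mismatch_rejected(tiny_flow):
    bad = MultiscaleLatent([np.zeros((1, 2, 8, 8)), np.zeros((1, 8, 2, 2))])
    with pytest.raises(ValueError):
        decode(tiny_flow, bad)


def test_encode_of_decode_recovers_latent(tiny_flow, rng):
    lat = tiny_flow.sample_latent(4, rng)
    x = decode(tiny_flow, lat)
    lat2, _ = encode(tiny_flow, x)
    assert np.max(np.abs(lat2.flatten() - lat.flatten())) <= 1e-4
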