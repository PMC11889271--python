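"""Block-level checks against naive nested-loop / stepwise oracles."""

import numpy as np
import pytest

import mrpunet.blocks as blocks
from mrpunet import nn
from mrpunet.blocks import (ConfigurationError, EncoderBlock, MIFConfig,
                            MIFInject, PDCBottleneck, PDCConfig, Res2NetBlock,
                            Res2SEConfig, SqueezeExcite, mif_build_pyramid,
                            pdc_receptive_field, se_squeeze)
from mrpunet.nn import functional as F
from mrpunet.nn.autograd import Tensor


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def naive_conv2d(x, w, b, dilation=1):
    """Quadruple-loop stride-1 'same' convolution oracle."""
    B, C, H, W = x.shape
    O, _, k, _ = w.shape
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, O, H, W))
    for bi in range(B):
        for o in range(O):
            for i in range(H):
                for j in range(W):
                    acc = 0.0
                    for c in range(C):
                        for u in range(k):
                            for v in range(k):
                                acc += (w[o, c, u, v]
                                        * xp[bi, c, i + u * dilation, j + v * dilation])
                    out[bi, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def identity_conv_weights(channels, k):
    """Kernel acting as the identity map (centre tap 1 per channel)."""
    w = np.zeros((channels, channels, k, k))
    for c in range(channels):
        w[c, c, k // 2, k // 2] = 1.0
    return w


# ---------------------------------------------------------------------------
# convolution vs loop oracle (foundation for every block)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dilation", [1, 2])
def test_conv2d_matches_loop_oracle(rng, dilation):
    x = rng.normal(size=(2, 3, 8, 8))
    w = rng.normal(size=(4, 3, 3, 3))
    b = rng.normal(size=4)
    got = F.conv2d(Tensor(x), Tensor(w), Tensor(b), dilation=dilation).data
    np.testing.assert_allclose(got, naive_conv2d(x, w, b, dilation), rtol=1e-5,
                               atol=1e-8)


# ---------------------------------------------------------------------------
# Res2Net
# ---------------------------------------------------------------------------

def test_res2net_group_width():
    cfg = Res2SEConfig(in_channels=64, out_channels=64, n_groups=4)
    assert cfg.group_channels == 16


def test_res2net_rejects_indivisible_channels():
    with pytest.raises(ConfigurationError):
        Res2SEConfig(in_channels=8, out_channels=10, n_groups=4)


def test_res2net_identity_seam_is_groupwise_prefix_sum(rng):
    """With every conv set to identity, the recurrence reduces to
    Y_1=X_1, Y_i=X_i+Y_{i-1}: a group-wise prefix sum, computed here by an
    explicit loop oracle."""
    cfg = Res2SEConfig(in_channels=8, out_channels=8, n_groups=4)
    block = Res2NetBlock(cfg, np.random.default_rng(0))
    block.proj.weight.data[...] = identity_conv_weights(8, 1)
    block.proj.bias.data[...] = 0
    block.fuse.weight.data[...] = identity_conv_weights(8, 1)
    block.fuse.bias.data[...] = 0
    for conv in block.group_convs:
        conv.weight.data[...] = identity_conv_weights(cfg.group_channels, 3)
        conv.bias.data[...] = 0

    x = rng.normal(size=(1, 8, 4, 4))
    got = block(Tensor(x)).data

    gc = cfg.group_channels
    groups = [x[:, i * gc:(i + 1) * gc] for i in range(4)]
    ys = [groups[0]]
    for i in range(1, 4):  # identity K_i: Y_i = X_i (+ Y_{i-1} for i>1)
        ys.append(groups[i] + (ys[-1] if i >= 2 else 0))
    expected = np.concatenate(ys, axis=1)
    np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-8)


def test_res2net_matches_stepwise_conv_oracle(rng):
    """Random weights: the block equals proj -> group recurrence -> concat ->
    fuse evaluated with the loop convolution oracle."""
    cfg = Res2SEConfig(in_channels=6, out_channels=8, n_groups=4)
    block = Res2NetBlock(cfg, np.random.default_rng(3))
    x = rng.normal(size=(2, 6, 5, 5))
    got = block(Tensor(x)).data

    h = naive_conv2d(x, block.proj.weight.data, block.proj.bias.data)
    gc = cfg.group_channels
    groups = [h[:, i * gc:(i + 1) * gc] for i in range(4)]
    ys = [groups[0]]
    for i in range(1, 4):
        inp = groups[i] + (ys[-1] if i >= 2 else 0)
        conv = block.group_convs[i - 1]
        ys.append(naive_conv2d(inp, conv.weight.data, conv.bias.data))
    expected = naive_conv2d(np.concatenate(ys, axis=1),
                            block.fuse.weight.data, block.fuse.bias.data)
    np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-7)


def test_res2net_shape_preservation(rng):
    cfg = Res2SEConfig(in_channels=16, out_channels=16, n_groups=4)
    block = Res2NetBlock(cfg, np.random.default_rng(0))
    out = block(Tensor(rng.normal(size=(2, 16, 32, 32)).astype(np.float32)))
    assert out.shape == (2, 16, 32, 32)
    with pytest.raises(ConfigurationError):
        block(Tensor(rng.normal(size=(2, 8, 32, 32))))


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

def test_se_squeeze_is_channel_mean(rng):
    x = np.full((1, 2, 3, 3), 3.0)
    np.testing.assert_allclose(se_squeeze(Tensor(x)).data, 3.0)

    plane = np.array([[0.0, 1.0], [2.0, 3.0]])
    x = plane[None, None]
    assert se_squeeze(Tensor(x)).data[0, 0] == pytest.approx(1.5)

    x = rng.normal(size=(1, 5, 7, 7))
    expected = np.zeros((1, 5))
    for c in range(5):  # explicit double-sum oracle
        acc = 0.0
        for i in range(7):
            for j in range(7):
                acc += x[0, c, i, j]
        expected[0, c] = acc / 49.0
    np.testing.assert_allclose(se_squeeze(Tensor(x)).data, expected, rtol=1e-10)


def test_se_excite_bounds_and_hidden_width(rng):
    se = SqueezeExcite(16, reduction=4, rng=np.random.default_rng(0))
    assert se.fc1.weight.data.shape == (4, 16)  # hidden width S/R

    z = Tensor(rng.normal(size=(3, 16)) * 10)
    w = se.excite(z).data
    assert np.all(w > 0) and np.all(w < 1)

    se.fc1.weight.data[...] = 0
    se.fc1.bias.data[...] = 0
    se.fc2.weight.data[...] = 0
    se.fc2.bias.data[...] = 0
    np.testing.assert_allclose(se.excite(z).data, 0.5)


def test_se_forward_stepwise_composition(rng):
    se = SqueezeExcite(8, reduction=2, rng=np.random.default_rng(5))
    x = rng.normal(size=(2, 8, 4, 4))
    got = se(Tensor(x)).data

    z = x.mean(axis=(2, 3))
    h = np.maximum(z @ se.fc1.weight.data.T + se.fc1.bias.data, 0)
    w = 1.0 / (1.0 + np.exp(-(h @ se.fc2.weight.data.T + se.fc2.bias.data)))
    np.testing.assert_allclose(got, x * w[:, :, None, None], rtol=1e-6)

    # zero input stays zero; nonzero planes are scaled by one constant
    assert np.all(se(Tensor(np.zeros((1, 8, 3, 3)))).data == 0)
    ratio = got / x
    for b in range(2):
        for c in range(8):
            np.testing.assert_allclose(ratio[b, c], ratio[b, c].flat[0], rtol=1e-5)


# ---------------------------------------------------------------------------
# Res2-SE composite
# ---------------------------------------------------------------------------

def test_res2se_order_and_composition(rng):
    """dropout 0 + BN eps 0 with unit running stats: the block equals
    relu(se(res2net(x))) computed stepwise."""
    cfg = Res2SEConfig(in_channels=4, out_channels=8, n_groups=4,
                       se_reduction=2, dropout_rate=0.0)
    block = EncoderBlock(cfg, np.random.default_rng(2))
    block.eval()
    block.bn.eps = 0.0  # test seam: BN with running (0,1) stats is identity
    x = rng.normal(size=(2, 4, 6, 6))
    got = block(Tensor(x)).data
    expected = np.maximum(block.se(block.body(Tensor(x))).data, 0)
    np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-8)


def test_res2se_eval_determinism_and_relu_floor(rng):
    cfg = Res2SEConfig(in_channels=4, out_channels=8, dropout_rate=0.3)
    block = EncoderBlock(cfg, np.random.default_rng(0))
    block.eval()
    x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
    a, b = block(x).data, block(x).data
    np.testing.assert_array_equal(a, b)
    assert a.min() >= 0
    assert np.isfinite(a).all()


# ---------------------------------------------------------------------------
# pyramid dilated convolution
# ---------------------------------------------------------------------------

def test_pdc_receptive_field_recurrence():
    rates = (1, 2, 4, 8)
    assert [pdc_receptive_field(rates, k) for k in (1, 2, 3, 4)] == [3, 7, 15, 31]
    # grows strictly with branch index for any valid rate list
    rf = [pdc_receptive_field((1, 3, 5), k) for k in (1, 2, 3)]
    assert rf == sorted(set(rf))


def test_pdc_zero_weights_residual_identity(rng):
    cfg = PDCConfig(channels=8)
    block = PDCBottleneck(cfg, np.random.default_rng(0))
    for conv in list(block.cascade) + [block.fuse]:
        conv.weight.data[...] = 0
        conv.bias.data[...] = 0
    x = rng.normal(size=(1, 8, 6, 6))
    np.testing.assert_array_equal(block(Tensor(x)).data, x)


def test_pdc_matches_cascade_oracle(rng):
    cfg = PDCConfig(channels=4, dilation_rates=(1, 2), residual=True)
    block = PDCBottleneck(cfg, np.random.default_rng(1))
    x = rng.normal(size=(2, 4, 8, 8))
    got = block(Tensor(x)).data

    c1 = naive_conv2d(x, block.cascade[0].weight.data,
                      block.cascade[0].bias.data, dilation=1)
    c2 = naive_conv2d(c1, block.cascade[1].weight.data,
                      block.cascade[1].bias.data, dilation=2)
    fused = naive_conv2d(np.concatenate([c1, c2], axis=1),
                         block.fuse.weight.data, block.fuse.bias.data)
    np.testing.assert_allclose(got, fused + x, rtol=1e-5, atol=1e-7)


def test_pdc_shape_and_validation(rng):
    block = PDCBottleneck(PDCConfig(channels=32), np.random.default_rng(0))
    out = block(Tensor(rng.normal(size=(1, 32, 36, 36)).astype(np.float32)))
    assert out.shape == (1, 32, 36, 36)
    with pytest.raises(ConfigurationError):
        block(Tensor(rng.normal(size=(1, 16, 36, 36))))
    with pytest.raises(ConfigurationError):
        PDCConfig(channels=8, dilation_rates=(2, 2, 4))


# ---------------------------------------------------------------------------
# multiscale input fusion
# ---------------------------------------------------------------------------

def test_pyramid_sides_and_constancy():
    cfg = MIFConfig(base_size=96, n_scales=4)
    assert cfg.sides == [96, 48, 24, 12]
    image = np.full((3, 96, 96), 0.37)
    levels = mif_build_pyramid(image, cfg)
    assert [lvl.shape[-1] for lvl in levels] == [96, 48, 24, 12]
    np.testing.assert_allclose(levels[0], image)  # level 0 untouched
    for lvl in levels:
        np.testing.assert_allclose(lvl, 0.37)

    with pytest.raises(ConfigurationError):
        MIFConfig(base_size=100, n_scales=4)


def test_pyramid_is_area_average(rng):
    cfg = MIFConfig(base_size=8, n_scales=2)
    image = rng.normal(size=(3, 8, 8))
    levels = mif_build_pyramid(image, cfg)
    expected = image.reshape(3, 4, 2, 4, 2).mean(axis=(2, 4))
    np.testing.assert_allclose(levels[1], expected)


def test_mif_inject_identities_and_oracle(rng):
    inject = MIFInject(8, np.random.default_rng(4))
    img = rng.normal(size=(2, 3, 6, 6))
    feat = rng.normal(size=(2, 8, 6, 6))

    got = inject(Tensor(img), Tensor(feat)).data
    expected = naive_conv2d(img, inject.proj.weight.data,
                            inject.proj.bias.data) + feat
    np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-7)

    inject.proj.weight.data[...] = 0
    inject.proj.bias.data[...] = 0
    np.testing.assert_array_equal(inject(Tensor(img), Tensor(feat)).data, feat)

    with pytest.raises(ValueError, match="6, 6"):
        inject(Tensor(rng.normal(size=(2, 3, 4, 4))), Tensor(feat))


def test_functional_wrappers_return_arrays(rng):
    cfg = Res2SEConfig(in_channels=4, out_channels=8)
    block = Res2NetBlock(cfg, np.random.default_rng(0))
    x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
    out = blocks.res2net_forward(x, block)
    assert isinstance(out, np.ndarray) and out.shape == (1, 8, 5, 5)
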