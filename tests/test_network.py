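"""Network assembly: shapes, ablation lattice, checkpoints, parameter counts."""

import numpy as np
import pytest

from mrpunet import nn
from mrpunet.blocks import ConfigurationError
from mrpunet.network import (ABLATION_MODULES, ModelConfig, ablation_config,
                             build_model, count_parameters, full_config,
                             load_checkpoint, save_checkpoint, tiny_config)
from mrpunet.nn import functional as F


@pytest.fixture
def x32(rng):
    return rng.random((2, 3, 32, 32)).astype(np.float32)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=100)  # not divisible by 2^4
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=96, level_channels=[6, 12, 24, 48])  # % n_groups
    cfg = tiny_config()
    assert cfg.input_size == 96 and cfg.mif_config().sides == [96, 48, 24, 12]


@pytest.mark.parametrize("module_name", sorted(ABLATION_MODULES))
def test_every_ablation_configuration_preserves_shape(module_name, x32,
                                                      small_model_config):
    cfg = ablation_config(module_name, base=small_model_config)
    model = build_model(cfg, seed=0)
    out = model.predict_scores(x32)
    assert out.shape == (2, cfg.n_classes, 32, 32)
    assert np.isfinite(out).all()


def test_eval_mode_forward_is_deterministic(x32, small_model_config):
    model = build_model(small_model_config, seed=3)
    np.testing.assert_array_equal(model.predict_scores(x32),
                                  model.predict_scores(x32))


def test_zero_weights_give_uniform_class_scores(small_model_config):
    model = build_model(small_model_config, seed=0)
    for p in model.parameters():
        p.data[...] = 0
    out = model.predict_scores(np.zeros((1, 3, 32, 32), dtype=np.float32))
    np.testing.assert_array_equal(out[:, 0], out[:, 1])


def test_forward_rejects_wrong_spatial_size(small_model_config, rng):
    model = build_model(small_model_config, seed=0)
    with pytest.raises(ValueError, match="32x32"):
        model(rng.random((1, 3, 16, 16)).astype(np.float32))


def test_baseline_matches_hand_assembled_unet(x32, small_model_config):
    """The all-switches-off configuration, with its weights copied into an
    independently hand-assembled plain U-Net, produces identical scores."""
    cfg = ablation_config("unet", base=small_model_config)
    model = build_model(cfg, seed=7)
    chans = cfg.level_channels
    rng = np.random.default_rng(0)

    class PlainUNet(nn.Module):
        def __init__(self):
            super().__init__()
            ins = [3] + chans[:-1]
            self.enc = nn.ModuleList()
            for cin, cout in zip(ins, chans):
                self.enc.append(nn.Sequential(
                    nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout),
                    nn.Conv2d(cout, cout, 3, rng), nn.BatchNorm2d(cout)))
            self.b1 = nn.Conv2d(chans[-1], cfg.bottleneck_channels, 3, rng)
            self.nb1 = nn.BatchNorm2d(cfg.bottleneck_channels)
            self.b2 = nn.Conv2d(cfg.bottleneck_channels, cfg.bottleneck_channels, 3, rng)
            self.nb2 = nn.BatchNorm2d(cfg.bottleneck_channels)
            self.up, self.dec = nn.ModuleList(), nn.ModuleList()
            for lvl in reversed(range(4)):
                cin = cfg.bottleneck_channels if lvl == 3 else chans[lvl + 1]
                self.up.append(nn.ConvTranspose2x2(cin, chans[lvl], rng))
                self.dec.append(nn.Sequential(
                    nn.Conv2d(2 * chans[lvl], chans[lvl], 3, rng),
                    nn.BatchNorm2d(chans[lvl]),
                    nn.Conv2d(chans[lvl], chans[lvl], 3, rng),
                    nn.BatchNorm2d(chans[lvl])))
            self.head = nn.Conv2d(chans[0], 2, 1, rng)

        def stage(self, seq, h):
            h = F.relu(seq.layers[1](seq.layers[0](h)))
            return F.relu(seq.layers[3](seq.layers[2](h)))

        def forward(self, h):
            skips = []
            for i, seq in enumerate(self.enc):
                h = self.stage(seq, h)
                skips.append(h)
                h = F.max_pool2x2(h)
            h = F.relu(self.nb1(self.b1(h)))
            h = F.relu(self.nb2(self.b2(h)))
            for i, lvl in enumerate(reversed(range(4))):
                h = self.up[i](h)
                h = F.concat([h, skips[lvl]], axis=1)
                h = self.stage(self.dec[i], h)
            return self.head(h)

    ref = PlainUNet()
    ref.eval()
    # copy weights across by positional correspondence of named parameters
    src = model.state_dict()
    dst_names = [n for n, _ in ref.named_parameters()]
    src_names = [n for n, _ in model.named_parameters()]
    assert len(dst_names) == len(src_names)
    mapping = {d: src[s] for d, s in zip(dst_names, src_names)}
    for n, b in ref.named_buffers():
        mapping["buffer:" + n] = b
    ref.load_state_dict(mapping)

    np.testing.assert_allclose(ref(nn.as_tensor(x32)).data,
                               model.predict_scores(x32), rtol=1e-5, atol=1e-6)


def test_parameter_counts_monotone(small_model_config):
    tiny = count_parameters(build_model(tiny_config(), seed=0))["total"]
    full = count_parameters(build_model(full_config(), seed=0))["total"]
    assert tiny < full

    base = count_parameters(build_model(
        ablation_config("unet", base=small_model_config), seed=0))["total"]
    full_cfg = count_parameters(build_model(
        ablation_config("mrp-unet", base=small_model_config), seed=0))["total"]
    assert base <= full_cfg

    with_pdc = build_model(small_model_config, seed=0)
    counts = count_parameters(with_pdc)
    assert counts["total"] == sum(v for k, v in counts.items() if k != "total")
    import dataclasses
    no_pdc = build_model(dataclasses.replace(small_model_config, use_pdc=False),
                         seed=0)
    assert count_parameters(no_pdc)["total"] < counts["total"]


def test_checkpoint_roundtrip_bit_identical(tmp_path, x32, small_model_config):
    model = build_model(small_model_config, seed=11)
    before = model.predict_scores(x32)
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    reloaded, tstate = load_checkpoint(path)
    assert tstate is None
    np.testing.assert_array_equal(before, reloaded.predict_scores(x32))
    assert reloaded.cfg == model.cfg and reloaded.seed == 11

    recount = count_parameters(reloaded)
    assert recount == count_parameters(model)


def test_checkpoint_mismatch_and_corruption_errors(tmp_path, small_model_config):
    model = build_model(small_model_config, seed=0)
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)

    import dataclasses
    other_cfg = dataclasses.replace(small_model_config,
                                    level_channels=[4, 8, 16])
    other = build_model(other_cfg, seed=0)
    with pytest.raises(ValueError, match="incompatible"):
        load_checkpoint(path, model=other)

    bad = tmp_path / "bad.ckpt"
    bad.write_bytes(b"not a checkpoint")
    with pytest.raises(ValueError):
        load_checkpoint(bad)
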