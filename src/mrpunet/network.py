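"""Assembly of the full segmentation network.

The architecture is a 4-level U-Net encoder-decoder over 2-class (lesion vs
skin) score maps, with three optional enhancements controlled by boolean
switches so that every ablation configuration is constructible:

* ``use_mif``   — an image pyramid of the input is injected into encoder
  levels 1..3 by 1x1 convolution + residual addition; the fused map feeds the
  level's block and is that level's skip-connection source.
* ``use_res2net`` / ``use_se`` — the encoder stage body is a Res2Net
  split-group block and/or gains SE channel attention (both on = the Res2-SE
  composite); both off = the conventional double 3x3 convolution.
* ``use_pdc``   — the bottleneck is a pyramid dilated-convolution block
  (after one channel-lifting convolution); off = a plain double convolution.

With all switches off the model is a plain U-Net. Decoder stages are
transposed-convolution upsampling, skip concatenation, then a double
convolution; the head is a 1x1 convolution to two class scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from . import nn
from .blocks import (ConfigurationError, DoubleConv, EncoderBlock, MIFConfig,
                     MIFInject, PDCBottleneck, PDCConfig, Res2SEConfig,
                     mif_build_pyramid)
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "ModelConfig", "MRPUNet", "build_model", "count_parameters",
    "save_checkpoint", "load_checkpoint", "tiny_config", "full_config",
    "ablation_config", "ABLATION_MODULES",
]

CHECKPOINT_FORMAT = "mrpunet-checkpoint-v1"


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``level_channels`` gives the encoder width per level (shallow to deep);
    the bottleneck sits one pooling below the deepest level. The full-size
    default works on 576x576 inputs with pyramid sides 576/288/144/72 and a
    36x36 bottleneck; :func:`tiny_config` scales everything down for CPU use.
    """

    input_size: int = 576
    in_channels: int = 3
    level_channels: List[int] = field(default_factory=lambda: [32, 64, 128, 256])
    bottleneck_channels: int = 512
    n_classes: int = 2
    n_groups: int = 4
    se_reduction: int = 16
    dropout_rate: float = 0.2
    dilation_rates: tuple = (1, 2, 4, 8)
    pdc_residual: bool = True
    bn_decay: float = 0.998
    use_mif: bool = True
    use_res2net: bool = True
    use_se: bool = True
    use_pdc: bool = True

    def __post_init__(self):
        if self.input_size % (2 ** self.n_levels):
            raise ConfigurationError(
                f"input_size={self.input_size} must be divisible by "
                f"2^{self.n_levels}")
        for c in self.level_channels:
            if c % self.n_groups:
                raise ConfigurationError(
                    f"level width {c} not divisible by n_groups={self.n_groups}")
        if self.bottleneck_channels % self.n_groups:
            raise ConfigurationError("bottleneck width not divisible by n_groups")

    @property
    def n_levels(self) -> int:
        return len(self.level_channels)

    @property
    def use_res2se(self) -> bool:
        return self.use_res2net or self.use_se

    def mif_config(self) -> MIFConfig:
        return MIFConfig(base_size=self.input_size, n_scales=self.n_levels,
                         per_scale_channels=list(self.level_channels[:-1]))

    def pdc_config(self) -> PDCConfig:
        return PDCConfig(channels=self.bottleneck_channels,
                         dilation_rates=self.dilation_rates,
                         residual=self.pdc_residual)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dilation_rates"] = tuple(d.get("dilation_rates", (1, 2, 4, 8)))
        return cls(**d)


def tiny_config(**overrides) -> ModelConfig:
    """CPU-scale preset: 96x96 inputs, widths [8, 16, 32, 64], bottleneck 128."""
    base = dict(input_size=96, level_channels=[8, 16, 32, 64],
                bottleneck_channels=128)
    base.update(overrides)
    return ModelConfig(**base)


def full_config(**overrides) -> ModelConfig:
    """Full-size preset for 576x576 dermoscopy inputs."""
    return ModelConfig(**overrides)


# The ablation lattice: module name -> (use_mif, use_res2net, use_se, use_pdc).
ABLATION_MODULES: Dict[str, tuple] = {
    "unet": (False, False, False, False),
    "unet+mif": (True, False, False, False),
    "unet+res2net": (False, True, False, False),
    "unet+se": (False, False, True, False),
    "unet+res2se": (False, True, True, False),
    "unet+pdc": (False, False, False, True),
    "unet+mif+res2se": (True, True, True, False),
    "unet+mif+pdc": (True, False, False, True),
    "unet+res2se+pdc": (False, True, True, True),
    "mrp-unet": (True, True, True, True),
}


def ablation_config(name: str, base: Optional[ModelConfig] = None) -> ModelConfig:
    """Config for one entry of the ten-configuration ablation lattice."""
    if name not in ABLATION_MODULES:
        raise KeyError(f"unknown ablation module {name!r}; "
                       f"choose from {sorted(ABLATION_MODULES)}")
    mif, r2, se, pdc = ABLATION_MODULES[name]
    base = base if base is not None else ModelConfig()
    return replace(base, use_mif=mif, use_res2net=r2, use_se=se, use_pdc=pdc)


class MRPUNet(nn.Module):
    """The assembled encoder-decoder. See module docstring for the layout."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        chans = cfg.level_channels
        L = cfg.n_levels

        def enc_cfg(cin, cout):
            return Res2SEConfig(cin, cout, cfg.n_groups, cfg.se_reduction,
                                cfg.dropout_rate)

        self.encoders = nn.ModuleList([
            EncoderBlock(enc_cfg(cfg.in_channels if lvl == 0 else chans[lvl - 1],
                                 chans[lvl]),
                         rng, use_res2net=cfg.use_res2net, use_se=cfg.use_se,
                         bn_decay=cfg.bn_decay, dropout_seed=self.seed + 101 + lvl)
            for lvl in range(L)
        ])
        if cfg.use_mif:
            # injections at levels 1..L-1 (level 0 sees the original image)
            self.mif_injects = nn.ModuleList(
                [MIFInject(chans[lvl - 1], rng, in_ch=cfg.in_channels)
                 for lvl in range(1, L)])

        self.bottleneck_lift = nn.Conv2d(chans[-1], cfg.bottleneck_channels, 3, rng)
        self.bottleneck_bn = nn.BatchNorm2d(cfg.bottleneck_channels, decay=cfg.bn_decay)
        if cfg.use_pdc:
            self.pdc = PDCBottleneck(cfg.pdc_config(), rng)
        else:
            self.bottleneck_conv2 = nn.Conv2d(cfg.bottleneck_channels,
                                              cfg.bottleneck_channels, 3, rng)
            self.bottleneck_bn2 = nn.BatchNorm2d(cfg.bottleneck_channels,
                                                 decay=cfg.bn_decay)

        # skip widths: level 0 is the block output; deeper levels depend on MIF
        skip_ch = [chans[0]] + [
            (chans[lvl - 1] if cfg.use_mif else chans[lvl]) for lvl in range(1, L)
        ]
        ups, decs = [], []
        for lvl in reversed(range(L)):
            cin = cfg.bottleneck_channels if lvl == L - 1 else chans[lvl + 1]
            ups.append(nn.ConvTranspose2x2(cin, chans[lvl], rng))
            decs.append(DoubleConv(chans[lvl] + skip_ch[lvl], chans[lvl], rng,
                                   cfg.bn_decay))
        self.ups = nn.ModuleList(ups)       # deepest level first
        self.decoders = nn.ModuleList(decs)
        self.head = nn.Conv2d(chans[0], cfg.n_classes, 1, rng)
        self.eval()

    # -- forward --------------------------------------------------------------

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = nn.as_tensor(x)
        cfg = self.cfg
        B, C, H, W = x.shape
        if (H, W) != (cfg.input_size, cfg.input_size):
            raise ValueError(
                f"input is {H}x{W}, model expects "
                f"{cfg.input_size}x{cfg.input_size}")
        if C != cfg.in_channels:
            raise ValueError(f"input has {C} channels, expected {cfg.in_channels}")

        pyramid = None
        if cfg.use_mif:
            pyramid = [nn.as_tensor(p, dtype=x.dtype)
                       for p in mif_build_pyramid(x.data, cfg.mif_config())]

        skips = []
        h = self.encoders[0](x)
        skips.append(h)
        h = F.max_pool2x2(h)
        for lvl in range(1, cfg.n_levels):
            if cfg.use_mif:
                h = self.mif_injects[lvl - 1](pyramid[lvl], h)
                skips.append(h)       # fused map is the skip source
                h = self.encoders[lvl](h)
            else:
                h = self.encoders[lvl](h)
                skips.append(h)
            h = F.max_pool2x2(h)

        h = F.relu(self.bottleneck_bn(self.bottleneck_lift(h)))
        if cfg.use_pdc:
            h = self.pdc(h)
        else:
            h = F.relu(self.bottleneck_bn2(self.bottleneck_conv2(h)))

        for i, lvl in enumerate(reversed(range(cfg.n_levels))):
            h = self.ups[i](h)
            h = F.concat([h, skips[lvl]], axis=1)
            h = self.decoders[i](h)
        return self.head(h)

    def predict_scores(self, x) -> np.ndarray:
        """Eval-mode forward returning raw class scores as an ndarray."""
        was_training = self.training
        self.eval()
        out = self.forward(x).data
        if was_training:
            self.train()
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> MRPUNet:
    return MRPUNet(cfg, seed=seed)


def count_parameters(model: MRPUNet) -> Dict[str, int]:
    """Parameter tally per top-level module group plus ``total``."""
    groups: Dict[str, int] = {}
    total = 0
    for name, p in model.named_parameters():
        group = name.split(".")[0]
        groups[group] = groups.get(group, 0) + p.data.size
        total += p.data.size
    groups["total"] = total
    return groups


# ---------------------------------------------------------------------------
# checkpointing: single-file npz holding config JSON + named arrays
# ---------------------------------------------------------------------------

def save_checkpoint(model: MRPUNet, path, training_state: Optional[dict] = None) -> None:
    """Write model config, seed, and all weights/buffers to ``path`` (.npz)."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": model.cfg.to_dict(),
        "seed": model.seed,
    }
    arrays = {"weights/" + k: v for k, v in model.state_dict().items()}
    if training_state is not None:
        meta["has_training_state"] = True
        arrays.update(_flatten_training_state(training_state))
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8).copy()
    with open(path, "wb") as fh:  # avoid numpy appending ".npz" to the name
        np.savez(fh, **arrays)


def load_checkpoint(path, model: Optional[MRPUNet] = None):
    """Rebuild (or load into) a model from a checkpoint file.

    Returns ``(model, training_state_or_None)``.  If ``model`` is given its
    config must equal the stored one, otherwise an incompatibility error is
    raised.
    """
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ValueError(f"cannot parse checkpoint {path}: {exc}") from exc
    if "__meta__" not in data:
        raise ValueError(f"{path} is not a recognised checkpoint (no metadata)")
    meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unsupported checkpoint format {meta.get('format')!r}")
    cfg = ModelConfig.from_dict(meta["config"])
    if model is None:
        model = MRPUNet(cfg, seed=int(meta["seed"]))
    elif model.cfg != cfg:
        raise ValueError(
            "checkpoint is incompatible with the supplied model: "
            f"stored config {cfg} != model config {model.cfg}")
    state = {k[len("weights/"):]: v for k, v in data.items()
             if k.startswith("weights/")}
    model.load_state_dict(state)
    model.eval()
    training_state = None
    if meta.get("has_training_state"):
        training_state = _unflatten_training_state(data)
    return model, training_state


def _flatten_training_state(state: dict) -> dict:
    out = {"train/t": np.asarray(state["t"]),
           "train/epoch": np.asarray(state.get("epoch", 0))}
    for i, m in enumerate(state["m"]):
        out[f"train/m{i}"] = m
    for i, v in enumerate(state["v"]):
        out[f"train/v{i}"] = v
    return out


def _unflatten_training_state(data: dict) -> dict:
    ms = sorted((k for k in data if k.startswith("train/m")),
                key=lambda s: int(s[len("train/m"):]))
    vs = sorted((k for k in data if k.startswith("train/v")),
                key=lambda s: int(s[len("train/v"):]))
    return {"t": int(data["train/t"]), "epoch": int(data["train/epoch"]),
            "m": [data[k] for k in ms], "v": [data[k] for k in vs]}
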