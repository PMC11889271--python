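"""Building blocks of the segmentation network.

Three ideas are combined here, each a pure ``[B, C, H, W] -> [B, C', H, W]``
transform that never changes the spatial size:

* **Res2Net split-group residual convolution** — after a 1x1 channel
  projection the feature map is split into ``n`` equal channel groups
  ``X_1..X_n``; group 1 passes through untouched, group 2 gets a 3x3
  convolution, and every later group is convolved after adding the previous
  group's output (``Y_i = K_i(X_i + Y_{i-1})``), so the effective receptive
  field grows with the group index.  The groups are re-concatenated and fused
  by a final 1x1 convolution.
* **Squeeze-and-excitation (SE) channel attention** — global average pooling
  squeezes each channel to a scalar, a two-layer bottleneck gate (ReLU then
  sigmoid) produces per-channel weights in (0, 1), and the input planes are
  rescaled by those weights.
* **Pyramid dilated convolution (PDC)** — a cascade of 3x3 convolutions at
  increasing dilation rates; the outputs after 1, 2, ... convolutions form the
  pyramid branches, which are concatenated and fused by a 1x1 convolution
  (optionally with a residual skip around the whole block).

The multiscale-input-fusion (MIF) helpers build an image pyramid of the
network input and inject each scale into the matching encoder level through a
1x1 convolution plus residual addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "Res2SEConfig", "PDCConfig", "MIFConfig",
    "Res2NetBlock", "SqueezeExcite", "EncoderBlock", "DoubleConv",
    "PDCBottleneck", "MIFInject",
    "se_squeeze", "se_excite", "se_forward", "res2net_forward", "res2se_forward",
    "pdc_forward", "mif_build_pyramid", "mif_inject", "pdc_receptive_field",
]


class ConfigurationError(ValueError):
    """Raised when a block configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class Res2SEConfig:
    """Hyperparameters of one encoder block.

    ``n_groups`` is the Res2Net scale (number of channel groups);
    ``se_reduction`` is the SE bottleneck ratio R (hidden width
    ``max(out_channels // R, 4)``); ``dropout_rate`` applies between the SE
    gate and the closing BatchNorm.
    """

    in_channels: int
    out_channels: int
    n_groups: int = 4
    se_reduction: int = 16
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.n_groups < 2:
            raise ConfigurationError(f"n_groups must be >= 2, got {self.n_groups}")
        if self.out_channels % self.n_groups:
            raise ConfigurationError(
                f"out_channels={self.out_channels} not divisible by "
                f"n_groups={self.n_groups}")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @property
    def group_channels(self) -> int:
        return self.out_channels // self.n_groups

    @property
    def se_hidden(self) -> int:
        return max(self.out_channels // self.se_reduction, 4)


@dataclass
class PDCConfig:
    """Bottleneck pyramid: one branch per dilation rate, strictly increasing."""

    channels: int
    dilation_rates: Sequence[int] = (1, 2, 4, 8)
    residual: bool = True

    def __post_init__(self):
        rates = list(self.dilation_rates)
        if len(rates) < 2:
            raise ConfigurationError("need at least two dilation branches")
        if any(r < 1 for r in rates):
            raise ConfigurationError("dilation rates must be positive")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(f"dilation rates must strictly increase: {rates}")
        self.dilation_rates = tuple(rates)


@dataclass
class MIFConfig:
    """Input image pyramid: ``n_scales`` halvings starting at ``base_size``.

    ``per_scale_channels`` lists the channel width at each encoder level that
    receives an injection (levels 1..n_scales-1).
    """

    base_size: int = 576
    n_scales: int = 4
    per_scale_channels: List[int] = field(default_factory=lambda: [32, 64, 128])

    def __post_init__(self):
        if self.n_scales < 2:
            raise ConfigurationError("n_scales must be >= 2")
        if self.base_size % (2 ** (self.n_scales - 1)):
            raise ConfigurationError(
                f"base_size={self.base_size} not divisible by "
                f"2^{self.n_scales - 1}")

    @property
    def sides(self) -> List[int]:
        return [self.base_size // (2 ** level) for level in range(self.n_scales)]


# ---------------------------------------------------------------------------
# Res2Net
# ---------------------------------------------------------------------------

class Res2NetBlock(nn.Module):
    """Split-group residual convolution.

    1x1 conv (in -> out) -> split into ``n`` groups -> hierarchical 3x3
    convolutions per the group recurrence -> concat -> 1x1 fusion conv.
    """

    def __init__(self, cfg: Res2SEConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        gc = cfg.group_channels
        self.proj = nn.Conv2d(cfg.in_channels, cfg.out_channels, 1, rng)
        # K_i exists for groups 2..n (group 1 is an identity pass-through)
        self.group_convs = nn.ModuleList(
            [nn.Conv2d(gc, gc, 3, rng) for _ in range(cfg.n_groups - 1)])
        self.fuse = nn.Conv2d(cfg.out_channels, cfg.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ConfigurationError(
                f"Res2Net expects {cfg.in_channels} input channels, got {x.shape[1]}")
        h = self.proj(x)
        gc = cfg.group_channels
        groups = [
            Tensor._node(h.data[:, i * gc:(i + 1) * gc], (h,),
                         _make_slice_backward(h.shape, i * gc, (i + 1) * gc))
            for i in range(cfg.n_groups)
        ]
        ys = [groups[0]]  # Y_1 = X_1
        y = self.group_convs[0](groups[1])  # Y_2 = K_2(X_2)
        ys.append(y)
        for i in range(2, cfg.n_groups):  # Y_i = K_i(X_i + Y_{i-1})
            y = self.group_convs[i - 1](F.add(groups[i], y))
            ys.append(y)
        return self.fuse(F.concat(ys, axis=1))


def _make_slice_backward(full_shape, lo, hi):
    def backward(g):
        gx = np.zeros(full_shape, dtype=g.dtype)
        gx[:, lo:hi] = g
        return (gx,)
    return backward


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

def se_squeeze(x: Tensor) -> Tensor:
    """Global average pooling: [B, C, H, W] -> per-channel means [B, C]."""
    return F.global_avg_pool(x)


class SqueezeExcite(nn.Module):
    """Two-FC excitation gate followed by channelwise rescaling."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def excite(self, z: Tensor) -> Tensor:
        return F.sigmoid(self.fc2(F.relu(self.fc1(z))))

    def forward(self, x: Tensor) -> Tensor:
        return F.channel_scale(x, self.excite(se_squeeze(x)))


# ---------------------------------------------------------------------------
# composite encoder blocks
# ---------------------------------------------------------------------------

class DoubleConv(nn.Module):
    """Classic U-Net stage: (3x3 conv -> BN -> ReLU) twice."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 bn_decay: float = 0.998):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch, decay=bn_decay)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch, decay=bn_decay)

    def forward(self, x: Tensor) -> Tensor:
        x = F.relu(self.bn1(self.conv1(x)))
        return F.relu(self.bn2(self.conv2(x)))


class EncoderBlock(nn.Module):
    """One encoder stage: feature body, optional SE, Dropout -> BN -> ReLU.

    The body is a Res2Net block when ``use_res2net`` (the attention variant of
    a 3x3 double convolution) and a plain double convolution otherwise; the
    closing Dropout/BN/ReLU tail is applied only when either attention piece
    is active, so that with both switched off the stage is exactly the
    conventional double-conv of a plain U-Net.
    """

    def __init__(self, cfg: Res2SEConfig, rng: np.random.Generator,
                 use_res2net: bool = True, use_se: bool = True,
                 bn_decay: float = 0.998, dropout_seed: int = 0):
        super().__init__()
        self.use_res2net, self.use_se = use_res2net, use_se
        self.cfg = cfg
        if use_res2net:
            self.body = Res2NetBlock(cfg, rng)
        else:
            self.body = DoubleConv(cfg.in_channels, cfg.out_channels, rng, bn_decay)
        if use_se:
            self.se = SqueezeExcite(cfg.out_channels, cfg.se_reduction, rng)
        if use_res2net or use_se:
            self.drop = nn.Dropout2d(cfg.dropout_rate, seed=dropout_seed)
            self.bn = nn.BatchNorm2d(cfg.out_channels, decay=bn_decay)

    def forward(self, x: Tensor) -> Tensor:
        h = self.body(x)
        if self.use_se:
            h = self.se(h)
        if self.use_res2net or self.use_se:
            h = F.relu(self.bn(self.drop(h)))
        return h


# ---------------------------------------------------------------------------
# pyramid dilated convolution
# ---------------------------------------------------------------------------

class PDCBottleneck(nn.Module):
    """Cascaded dilated-convolution pyramid with 1x1 fusion.

    The cascade is shared: stage k convolves the previous stage's output at
    ``rates[k]``, so branch k's feature has passed k convolutions at rates
    ``rates[:k]`` and its receptive field along one axis is
    ``1 + 2 * sum(rates[:k])``.  Branch outputs are concatenated, fused back
    to ``channels`` by a 1x1 convolution, and (by default) the block input is
    added residually.
    """

    def __init__(self, cfg: PDCConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.cascade = nn.ModuleList(
            [nn.Conv2d(c, c, 3, rng, dilation=r) for r in cfg.dilation_rates])
        self.fuse = nn.Conv2d(c * len(cfg.dilation_rates), c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"PDC expects {self.cfg.channels} channels, got {x.shape[1]}")
        branches = []
        h = x
        for conv in self.cascade:
            h = conv(h)
            branches.append(h)
        out = self.fuse(F.concat(branches, axis=1))
        if self.cfg.residual:
            out = F.add(out, x)
        return out


def pdc_receptive_field(rates: Sequence[int], branch: int) -> int:
    """Receptive field (one axis) of pyramid branch ``branch`` (1-based).

    Each 3x3 convolution at dilation d grows the field by 2*d, starting
    from a single pixel.
    """
    if not 1 <= branch <= len(rates):
        raise ValueError(f"branch {branch} out of range for {len(rates)} rates")
    r = 1
    for d in list(rates)[:branch]:
        r += 2 * d
    return r


# ---------------------------------------------------------------------------
# multiscale input fusion
# ---------------------------------------------------------------------------

def mif_build_pyramid(image: np.ndarray, cfg: MIFConfig) -> List[np.ndarray]:
    """Image pyramid by area averaging.

    ``image`` is channel-first ``[3, S, S]`` (or batched ``[B, 3, S, S]``)
    with ``S == cfg.base_size``.  Level 0 is the input itself; level l is
    downsampled by 2**l using exact block means, which is deterministic and
    alias-free for the power-of-two ratios used here.
    """
    image = np.asarray(image)
    batched = image.ndim == 4
    if not batched:
        image = image[None]
    B, C, H, W = image.shape
    if H != cfg.base_size or W != cfg.base_size:
        raise ConfigurationError(
            f"pyramid input is {H}x{W}, expected {cfg.base_size}x{cfg.base_size}")
    levels = []
    for level in range(cfg.n_scales):
        f = 2 ** level
        if level == 0:
            out = image
        else:
            out = image.reshape(B, C, H // f, f, W // f, f).mean(axis=(3, 5))
        levels.append(out if batched else out[0])
    return levels


class MIFInject(nn.Module):
    """Fuse one pyramid level into its encoder feature.

    A 1x1 convolution lifts the 3-channel scaled image to the encoder width;
    the result is added residually.  The fused map both feeds the level's
    encoder block and becomes that level's skip-connection source.
    """

    def __init__(self, channels: int, rng: np.random.Generator, in_ch: int = 3):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, channels, 1, rng)

    def forward(self, scaled_image: Tensor, encoder_feature: Tensor) -> Tensor:
        if scaled_image.shape[2:] != encoder_feature.shape[2:]:
            raise ValueError(
                f"MIF injection: image size {scaled_image.shape[2:]} != "
                f"feature size {encoder_feature.shape[2:]}")
        return F.add(self.proj(scaled_image), encoder_feature)


# ---------------------------------------------------------------------------
# thin functional wrappers (library surface)
# ---------------------------------------------------------------------------

def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else nn.as_tensor(x)


def res2net_forward(x, block: Res2NetBlock) -> np.ndarray:
    return block(_wrap(x)).data


def se_excite(z, se: SqueezeExcite) -> np.ndarray:
    return se.excite(_wrap(z)).data


def se_forward(x, se: SqueezeExcite) -> np.ndarray:
    return se(_wrap(x)).data


def res2se_forward(x, block: EncoderBlock, training: bool = False) -> np.ndarray:
    block.train(training)
    out = block(_wrap(x)).data
    block.eval()
    return out


def pdc_forward(x, block: PDCBottleneck) -> np.ndarray:
    return block(_wrap(x)).data


def mif_inject(scaled_image, encoder_feature, inject: MIFInject) -> np.ndarray:
    return inject(_wrap(scaled_image), _wrap(encoder_feature)).data
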