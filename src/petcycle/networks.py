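"""Generator and critic architectures for cycle-consistent PET denoising.

Two symmetric generators map between the low-dose and standard-dose image
domains.  Each generator is a U-Net with stride-2 convolutional
downsampling (five stages by default, taking a 256x256 input to an 8x8
bottleneck), transposed-convolution upsampling with skip connections,
residual blocks at the deepest skip junctions, and an extra stride-1
refinement stage onto which the raw input image can be concatenated so
that fine structure survives the encoder-decoder funnel.  Critics are
multi-scale PatchGANs: the same stack of spectrally normalized stride-2
convolutions applied to the image and to average-pooled copies of it,
emitting one unbounded patch-score map per scale (Wasserstein critics
carry no output nonlinearity).

The ablation axes studied with this model family — downsampling depth,
residual blocks on/off, input concatenation on/off, adversarial loss
flavour — are all plain configuration flags.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


class ConfigError(ValueError):
    """Invalid architecture configuration."""


@dataclass
class GeneratorConfig:
    n_down: int = 5
    n_up: int | None = None          # defaults to n_down + 1 (refinement stage)
    base_channels: int = 64
    max_channel_mult: int = 8
    norm_kind: str = "instance"      # "instance" or "batch"
    use_residual_blocks: bool = True
    n_residual_blocks: int = 4
    concat_input: bool = True
    identity_init: bool = True       # start the output stage near identity
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.n_up is None:
            self.n_up = self.n_down + 1
        if self.n_down < 1:
            raise ConfigError("n_down must be >= 1")
        if self.norm_kind not in ("instance", "batch"):
            raise ConfigError(f"unknown norm kind {self.norm_kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CriticConfig:
    n_scales: int = 3
    scale_factor: int = 2
    n_layers_per_scale: int = 4
    base_channels: int = 64
    max_channel_mult: int = 8
    spectral_norm: bool = True
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.n_scales < 1:
            raise ConfigError("n_scales must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def bottleneck_size(cfg: GeneratorConfig, input_side: int) -> int:
    """Spatial side length of the deepest encoder feature map."""
    div = 2 ** cfg.n_down
    if input_side % div:
        raise ConfigError(
            f"input side {input_side} not divisible by 2^{cfg.n_down}")
    return input_side // div


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with rectifier activations and an additive skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.relu(self.conv1(x))
        y = self.conv2(y)
        return ad.relu(x + y)


class Generator(nn.Module):
    """Residual U-Net generator; maps [-1, 1] images to [-1, 1] images."""

    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = [min(cfg.base_channels * 2 ** i,
                  cfg.base_channels * cfg.max_channel_mult)
              for i in range(cfg.n_down)]
        self._ch = ch
        slope = cfg.leaky_slope

        # encoder: stride-2 conv blocks; output i lives at side / 2^(i+1)
        self.enc = nn.Sequential(*[
            nn.Sequential(
                nn.Conv2d(1 if i == 0 else ch[i - 1], ch[i], stride=2,
                          rng=rng),
                nn.make_norm(cfg.norm_kind, ch[i]),
                nn.LeakyReLU(slope))
            for i in range(cfg.n_down)])

        self.bottleneck = nn.Sequential(
            nn.Conv2d(ch[-1], ch[-1], rng=rng),
            nn.make_norm(cfg.norm_kind, ch[-1]),
            nn.LeakyReLU(slope))

        # decoder: n_down transposed-conv stages with skip concatenation,
        # plus a final stride-1 refinement stage (the extra "up" stage)
        ups, merges = [], []
        res_per_junction = self._residual_layout()
        self.res_blocks = nn.Sequential()  # flat container for counting
        res_modules: list[list[ResidualBlock]] = []
        for j in range(cfg.n_down):
            in_ch = ch[cfg.n_down - 1 - j]
            out_ch = ch[cfg.n_down - 2 - j] if j < cfg.n_down - 1 \
                else cfg.base_channels
            ups.append(nn.Sequential(
                nn.ConvTranspose2d(in_ch, out_ch, rng=rng),
                nn.make_norm(cfg.norm_kind, out_ch),
                nn.ReLU()))
            if j < cfg.n_down - 1:      # junction with encoder skip
                merges.append(nn.Sequential(
                    nn.Conv2d(2 * out_ch, out_ch, rng=rng),
                    nn.make_norm(cfg.norm_kind, out_ch),
                    nn.ReLU()))
                blocks = [ResidualBlock(out_ch, rng)
                          for _ in range(res_per_junction[j])]
                res_modules.append(blocks)
                for b in blocks:
                    idx = len(self.res_blocks.layers)
                    self.res_blocks.layers.append(b)
                    self.res_blocks._children[str(idx)] = b
        self.ups = nn.Sequential(*ups)
        self.merges = nn.Sequential(*merges)
        self._res_modules = res_modules

        refine_in = cfg.base_channels + (1 if cfg.concat_input else 0)
        self.refine = nn.Sequential(
            nn.Conv2d(refine_in, cfg.base_channels, rng=rng),
            nn.make_norm(cfg.norm_kind, cfg.base_channels),
            nn.ReLU())
        head_in = cfg.base_channels + (1 if cfg.concat_input else 0)
        self.head = nn.Conv2d(head_in, 1, rng=rng)
        if cfg.concat_input and cfg.identity_init:
            # near-identity start: the head passes the raw input through
            # (center tap of the input channel = 1) and sees the learned
            # features only at small scale, so training begins from
            # "output = tanh(input)" and learns the denoising correction
            self.head.weight.data *= 0.01
            center = cfg.base_channels * 9 + 4     # input chan, 3x3 center
            self.head.weight.data[center, 0] = 1.0

    def _residual_layout(self) -> list[int]:
        """Residual blocks per decoder junction (index 0 = deepest)."""
        cfg = self.cfg
        n_junctions = cfg.n_down - 1
        counts = [0] * max(n_junctions, 1)
        if cfg.use_residual_blocks and n_junctions > 0:
            slots = min(3, n_junctions)
            for k in range(cfg.n_residual_blocks):
                counts[k % slots] += 1
        return counts

    def residual_parameter_count(self) -> int:
        return sum(b.n_parameters()
                   for blocks in self._res_modules for b in blocks)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        side = x.shape[-1]
        if side % (2 ** cfg.n_down) or x.shape[-2] % (2 ** cfg.n_down):
            raise ConfigError(
                f"input side {x.shape[-2:]} not divisible by 2^{cfg.n_down}")
        skips = []
        h = x
        for stage in self.enc.layers:
            h = stage(h)
            skips.append(h)
        h = self.bottleneck(h)
        for j in range(cfg.n_down):
            h = self.ups.layers[j](h)
            if j < cfg.n_down - 1:
                skip = skips[cfg.n_down - 2 - j]
                h = ad.concatenate([h, skip], axis=1)
                h = self.merges.layers[j](h)
                for block in self._res_modules[j]:
                    h = block(h)
        if cfg.concat_input:
            h = ad.concatenate([h, x], axis=1)
        h = self.refine(h)
        if cfg.concat_input:
            h = ad.concatenate([h, x], axis=1)
        return ad.tanh(self.head(h))


class MultiScaleCritic(nn.Module):
    """Multi-scale PatchGAN critic; returns one score map per scale."""

    def __init__(self, cfg: CriticConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.pool = nn.AvgPool2d(cfg.scale_factor)
        subs = []
        self.sn_layers: list[nn.SpectralNorm] = []
        for _ in range(cfg.n_scales):
            layers: list[nn.Module] = []
            in_ch = 1
            for layer_i in range(cfg.n_layers_per_scale):
                out_ch = min(cfg.base_channels * 2 ** layer_i,
                             cfg.base_channels * cfg.max_channel_mult)
                conv = nn.Conv2d(in_ch, out_ch, stride=2, rng=rng)
                layers.append(self._wrap(conv, rng))
                layers.append(nn.LeakyReLU(cfg.leaky_slope))
                in_ch = out_ch
            head = nn.Conv2d(in_ch, 1, stride=1, rng=rng)
            layers.append(self._wrap(head, rng))
            subs.append(nn.Sequential(*layers))
        self.subs = nn.Sequential(*subs)

    def _wrap(self, conv: nn.Conv2d, rng: np.random.Generator) -> nn.Module:
        if self.cfg.spectral_norm:
            sn = nn.SpectralNorm(conv, rng=rng)
            self.sn_layers.append(sn)
            return sn
        return conv

    def forward(self, x: Tensor) -> list[Tensor]:
        cfg = self.cfg
        min_side = min(x.shape[-2:]) // cfg.scale_factor ** (cfg.n_scales - 1)
        if min_side < 2 ** cfg.n_layers_per_scale:
            raise ConfigError(
                "input too small for the coarsest critic scale")
        outs = []
        for k, sub in enumerate(self.subs.layers):
            outs.append(sub(x))
            if k < cfg.n_scales - 1:
                x = self.pool(x)
        return outs


def fused_score(scores) -> Tensor:
    """Collapse critic output to one scalar score per sample.

    Each patch-score map is mean-reduced over channels and space, then the
    per-scale scalars are averaged.  Accepts a single map, a list of maps,
    or an already per-sample score vector.
    """
    if isinstance(scores, Tensor):
        scores = [scores]
    per_scale = []
    for s in scores:
        if s.ndim > 1:
            s = ad.mean_(s, axis=tuple(range(1, s.ndim)))
        per_scale.append(s)
    total = per_scale[0]
    for s in per_scale[1:]:
        total = total + s
    return total / float(len(per_scale))


def build_generator(cfg: GeneratorConfig, seed: int) -> Generator:
    """Deterministically construct a generator from (cfg, seed)."""
    return Generator(cfg, seed=seed)


def build_critic(cfg: CriticConfig, seed: int) -> MultiScaleCritic:
    """Deterministically construct a multi-scale critic from (cfg, seed)."""
    return MultiScaleCritic(cfg, seed=seed)
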