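"""Loss suite for cycle-consistent Wasserstein adversarial denoising.

The total generator objective is

    L = lambda_idt * L_idt + lambda_cycle * L_cycle + L_adv
        + lambda_pept * L_pept

with an L1 perceptual term computed in the feature space of a fixed
convolutional extractor, a WGAN adversarial term whose critic is
regularized by a gradient penalty (weight 10 by default), L1 cycle
consistency in both directions, and an L1 identity term.  A
least-squares (MSE) adversarial variant is provided as the ablation
baseline of the non-Wasserstein model family.

Sign conventions: critics are trained by *minimizing*
``E[D(fake)] - E[D(real)] + gp``; generators minimize ``-E[D(fake)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .networks import fused_score


class ShapeError(ValueError):
    pass


class WeightsUnavailableError(RuntimeError):
    """Pretrained feature-extractor weights are not present locally."""


@dataclass
class LossWeights:
    """Coefficients of the total objective (adversarial weight is 1)."""

    lambda_idt: float = 5.0
    lambda_cycle: float = 10.0
    lambda_pept: float = 1.0
    lambda_gp: float = 10.0

    def __post_init__(self):
        if min(self.lambda_idt, self.lambda_cycle,
               self.lambda_pept, self.lambda_gp) < 0:
            raise ValueError("loss weights must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LossBundle:
    """Evaluated loss terms of one training step (floats, generator side)."""

    adv_g: float = 0.0
    adv_d: float = 0.0
    cycle: float = 0.0
    identity: float = 0.0
    perceptual: float = 0.0
    total: float = 0.0

    def as_row(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# per-sample L1 helper: sum |a-b| over all non-batch axes, mean over batch
# ---------------------------------------------------------------------------

def _batch_l1(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = ad.absolute(a - b)
    return ad.mean_(ad.sum_(diff, axis=tuple(range(1, diff.ndim))))


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def perceptual_loss(phi, generated, target) -> Tensor:
    """Mean-over-batch L1 distance between feature maps of the two batches."""
    generated, target = ad.astensor(generated), ad.astensor(target)
    if generated.shape != target.shape:
        raise ShapeError(
            f"batch shape mismatch {generated.shape} vs {target.shape}")
    return _batch_l1(phi(generated), phi(target))


def cycle_loss(ga, gb, xa, xb) -> Tensor:
    """Forward (A->B->A) plus backward (B->A->B) L1 cycle consistency."""
    xa, xb = ad.astensor(xa), ad.astensor(xb)
    forward = _batch_l1(gb(ga(xa)), xa)
    backward = _batch_l1(ga(gb(xb)), xb)
    return forward + backward


def identity_loss(ga, gb, xa, xb) -> Tensor:
    """Penalty for altering inputs already in the generator's target domain."""
    xa, xb = ad.astensor(xa), ad.astensor(xb)
    return _batch_l1(ga(xb), xb) + _batch_l1(gb(xa), xa)


def generator_adv_loss(critic, fake) -> Tensor:
    """Wasserstein generator term: minimize -E[D(fake)]."""
    return -ad.mean_(fused_score(critic(ad.astensor(fake))))


def adv_loss_mse(critic, batch, target_label: float) -> Tensor:
    """Least-squares adversarial loss against a 0/1 target label
    (the MSE ablation baseline), averaged over all score-map elements."""
    scores = critic(ad.astensor(batch))
    if isinstance(scores, Tensor):
        scores = [scores]
    terms = [ad.mean_((s - float(target_label)) ** 2) for s in scores]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / float(len(terms))


def gradient_penalty(critic, real, fake, rng: np.random.Generator) -> Tensor:
    """(||grad_xhat D(xhat)||_2 - 1)^2 on per-sample random interpolates."""
    real, fake = ad.astensor(real), ad.astensor(fake)
    if real.shape != fake.shape:
        raise ShapeError("real/fake shape mismatch")
    b = real.shape[0]
    eps = rng.uniform(size=(b,) + (1,) * (real.ndim - 1)) \
        .astype(real.data.dtype)
    xhat = ad.Tensor(eps * real.data + (1.0 - eps) * fake.data)
    xhat.requires_grad = True
    score = ad.sum_(fused_score(critic(xhat)))
    gx, = ad.grad(score, [xhat], create_graph=True)
    sq = ad.sum_(gx * gx, axis=tuple(range(1, gx.ndim)))
    norm = ad.sqrt(sq + 1e-12)
    return ad.mean_((norm - 1.0) ** 2)


def critic_loss_wgan_gp(critic, real, fake, lambda_gp: float = 10.0,
                        seed: int | np.random.Generator = 0) -> Tensor:
    """Critic objective: E[D(fake)] - E[D(real)] + lambda * penalty."""
    real, fake = ad.astensor(real), ad.astensor(fake)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    gap = ad.mean_(fused_score(critic(fake))) \
        - ad.mean_(fused_score(critic(real)))
    loss = gap + float(lambda_gp) * gradient_penalty(critic, real, fake, rng)
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite critic loss")
    return loss


def total_loss(adv_g, cycle, identity, perceptual,
               weights: LossWeights) -> Tensor:
    """Weighted total generator objective (adversarial weight fixed at 1)."""
    return (weights.lambda_idt * ad.astensor(identity)
            + weights.lambda_cycle * ad.astensor(cycle)
            + ad.astensor(adv_g)
            + weights.lambda_pept * ad.astensor(perceptual))


# ---------------------------------------------------------------------------
# feature extractors for the perceptual term
# ---------------------------------------------------------------------------

class RandomConvFeatures(nn.Module):
    """Fixed, seeded two-stage convolutional feature extractor.

    A frozen random convolutional stack is a standard stand-in feature
    space for perceptual losses when no pretrained classifier is wanted:
    random convolutions preserve image information (they are almost surely
    injective on natural images) while mixing local context, so an L1
    distance in this space behaves like a structure-aware image distance.
    Parameters are frozen (no gradient is taken with respect to them).
    """

    def __init__(self, seed: int = 0, channels: int = 16):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(1, channels, rng=rng, init_std=0.1)
        self.conv2 = nn.Conv2d(channels, channels, stride=1, rng=rng,
                               init_std=0.1)
        for p in self.parameters():
            p.requires_grad = False
        self.descriptor = f"seeded_random_conv(seed={seed}, ch={channels})"

    def forward(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(self.conv2(ad.leaky_relu(self.conv1(x))))


class VGG19Conv16Features(nn.Module):
    """Feature tap at the 16th convolutional layer of VGG-19.

    Requires a local ``.npz`` file holding the VGG-19 convolution kernels as
    ``conv{i}_weight`` (HWIO or OIHW, see loader) and ``conv{i}_bias`` for
    i = 1..16.  Single-channel input is replicated to three channels and
    standardized with the usual ImageNet statistics before the stack.
    """

    MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
    STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)
    # channels of conv layers 1..16 and the pooling positions before them
    CHANNELS = [64, 64, 128, 128, 256, 256, 256, 256,
                512, 512, 512, 512, 512, 512, 512, 512]
    POOL_BEFORE = {3, 5, 9, 13}   # a 2x2 max/avg pool precedes these layers

    def __init__(self, weights_path: str | Path):
        super().__init__()
        path = Path(weights_path)
        if not path.exists():
            raise WeightsUnavailableError(
                f"VGG-19 weights not found at {path}; download the kernels "
                "to an .npz archive (keys conv1_weight..conv16_bias) or use "
                "kind='seeded_random_conv' which needs no external weights")
        archive = np.load(path)
        self.convs: list[nn.Conv2d] = []
        in_ch = 3
        holder = nn.Sequential()
        for i, out_ch in enumerate(self.CHANNELS, start=1):
            conv = nn.Conv2d(in_ch, out_ch, kernel=3, stride=1)
            w = archive[f"conv{i}_weight"]
            if w.ndim != 4:
                raise ValueError(f"conv{i}_weight must be 4-D")
            if w.shape[0] == out_ch:          # OIHW -> (I*KH*KW, O)
                w = np.transpose(w, (1, 2, 3, 0))
            conv.weight.data[...] = w.reshape(-1, out_ch)
            conv.bias.data[...] = archive[f"conv{i}_bias"]
            self.convs.append(conv)
            idx = len(holder.layers)
            holder.layers.append(conv)
            holder._children[str(idx)] = conv
            in_ch = out_ch
        self.stack = holder
        for p in self.parameters():
            p.requires_grad = False
        self.pool = nn.AvgPool2d(2)
        self.descriptor = f"vgg19_conv16({path})"

    def forward(self, x: Tensor) -> Tensor:
        rgb = ad.concatenate([x, x, x], axis=1)
        mean = self.MEAN.reshape(1, 3, 1, 1)
        std = self.STD.reshape(1, 3, 1, 1)
        h = (rgb - ad.Tensor(mean)) / ad.Tensor(std)
        for i, conv in enumerate(self.convs, start=1):
            if i in self.POOL_BEFORE:
                h = self.pool(h)
            h = conv(h)
            if i < len(self.convs):
                h = ad.relu(h)
        return h


def build_feature_extractor(kind: str, seed: int = 0,
                            weights_path: str | Path | None = None):
    """Construct the perceptual-loss feature extractor.

    kind = "seeded_random_conv" (default, self-contained) or
    "pretrained_vgg19_conv16" (needs a local weights archive).
    """
    if kind == "seeded_random_conv":
        return RandomConvFeatures(seed=seed)
    if kind == "pretrained_vgg19_conv16":
        if weights_path is None:
            raise WeightsUnavailableError(
                "kind='pretrained_vgg19_conv16' needs weights_path pointing "
                "to a local VGG-19 .npz archive; none was given. Use "
                "kind='seeded_random_conv' for a self-contained extractor.")
        return VGG19Conv16Features(weights_path)
    raise ValueError(f"unknown feature extractor kind {kind!r}")
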