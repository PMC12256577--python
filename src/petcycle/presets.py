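"""Canonical run configurations.

``paper_scale`` mirrors the published training protocol (256x256 inputs,
five downsamplings, 64 base channels, batch 32, 60 epochs, lr 1e-4,
warm restarts T0=10 / Tmult=2) and is what a GPU-backed run would use.

``desk_scale`` is the CPU-sized analogue used by the test suite and the
acceptance run: 64x64 phantoms, 8 base channels, three downsamplings,
200 low/standard-dose pairs, 8 epochs.  It exists to demonstrate the
same qualitative outcome — the trained model beats the low-dose input
against ground truth — at a problem size a single CPU handles in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .losses import LossWeights
from .networks import CriticConfig, GeneratorConfig
from .pet_io import NormalizationWindow
from .phantom import PhantomSpec
from .training import TrainConfig


@dataclass(frozen=True)
class DeskScale:
    """Desk-scale study conditions (shared by tests and acceptance)."""

    image_size: int = 64
    n_phantoms: int = 25
    slices_per_phantom: int = 8          # 200 pairs total
    epochs: int = 8
    batch_size: int = 2
    lr: float = 3e-3
    base_channels: int = 8
    n_down: int = 3
    n_residual_blocks: int = 2


DESK = DeskScale()


def paper_scale_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        epochs=60, batch_size=32, lr=1e-4, sched_T0=10, sched_Tmult=2,
        n_critic=5, seed=seed, image_side=256,
        generator=GeneratorConfig(),           # 5 down / 6 up, 64 channels
        critic=CriticConfig(),                 # 3 scales, spectral norm
        loss_weights=LossWeights(),
        window=NormalizationWindow(-15.0, 30.0))


def desk_scale_phantom_spec() -> PhantomSpec:
    return PhantomSpec(image_size=DESK.image_size)


def desk_scale_train_config(seed: int = 0) -> TrainConfig:
    """Small but real training run: same loss suite and architecture
    family, scaled so 200 pairs x 8 epochs fit in CPU minutes."""
    return TrainConfig(
        epochs=DESK.epochs, batch_size=DESK.batch_size, lr=DESK.lr,
        sched_T0=DESK.epochs, sched_Tmult=2, n_critic=1, seed=seed,
        image_side=DESK.image_size, perceptual_channels=8,
        generator=GeneratorConfig(n_down=DESK.n_down,
                                  base_channels=DESK.base_channels,
                                  n_residual_blocks=DESK.n_residual_blocks),
        critic=CriticConfig(base_channels=DESK.base_channels,
                            n_layers_per_scale=3),
        loss_weights=LossWeights(lambda_idt=1.0, lambda_cycle=1.0,
                                 lambda_pept=30.0),
        window=NormalizationWindow(-15.0, 30.0))
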