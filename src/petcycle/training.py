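"""Adversarial training of the two generator/critic pairs.

One training step performs ``n_critic`` critic updates (both critics,
Wasserstein loss with gradient penalty, or the least-squares ablation
variant) followed by one joint generator update minimizing the weighted
total of adversarial, cycle, identity and perceptual terms.  Both Adam
optimizers use the (0.5, 0.999) moment decays and a cosine-annealing
warm-restart learning-rate schedule (initial cycle length T0 epochs,
cycle growth factor Tmult).

All randomness (data order, gradient-penalty interpolates) derives from
the single run seed through fixed stream labels, so runs are exactly
reproducible and each stream is independently replayable.  Checkpoints
store the four networks, the optimizer moments, the normalization
window and the full configuration; training can resume from any epoch
boundary and continue exactly as the uninterrupted run would have.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import losses as L
from . import nn
from .networks import (CriticConfig, Generator, GeneratorConfig,
                       build_critic, build_generator, fused_score)
from .pet_io import NormalizationWindow, PETVolume, denormalize, normalize, \
    resample_slice
from .evaluation import psnr, read_manifest


class DataError(ValueError):
    pass


class NumericError(FloatingPointError):
    pass


def derive_seed(seed: int, label: str, index: int = 0) -> int:
    """Stable sub-seed (< 2^31) for a named randomness stream."""
    ss = np.random.SeedSequence(
        [seed, zlib.crc32(label.encode()) % (2 ** 31), index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    lr: float = 1e-4
    min_lr: float = 0.0
    beta1: float = 0.5
    beta2: float = 0.999
    sched_T0: int = 10
    sched_Tmult: int = 2
    n_critic: int = 5
    seed: int = 0
    mode: str = "paired"                 # paired | unpaired
    adv_kind: str = "wgan_gp"            # wgan_gp | mse
    image_side: int = 256
    crop_size: int | None = None         # optional random-crop side length
    clip_grad_norm: float | None = 5.0   # global-norm gradient clipping
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    critic: CriticConfig = field(default_factory=CriticConfig)
    window: NormalizationWindow = field(default_factory=NormalizationWindow)
    feature_seed: int = 1234
    perceptual_channels: int = 16

    def __post_init__(self):
        if self.epochs < 1 or self.n_critic < 1 or self.lr <= 0:
            raise ValueError("epochs/n_critic >= 1 and lr > 0 required")
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.adv_kind not in ("wgan_gp", "mse"):
            raise ValueError(f"unknown adversarial kind {self.adv_kind!r}")
        if self.crop_size is not None:
            div = 2 ** self.generator.n_down
            if self.crop_size % div or self.crop_size < div:
                raise ValueError(
                    f"crop_size must be a multiple of 2^n_down = {div}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key, klass in (("loss_weights", L.LossWeights),
                           ("generator", GeneratorConfig),
                           ("critic", CriticConfig),
                           ("window", NormalizationWindow)):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)


def clip_gradients(grads: list[np.ndarray], max_norm: float | None
                   ) -> list[np.ndarray]:
    """Scale the gradient list so its global L2 norm is at most max_norm.

    Loss spikes are routine in adversarial training; without clipping a
    single spike poisons the optimizer's second moments for many steps.
    """
    if max_norm is None:
        return grads
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return [g * scale for g in grads]


def random_crop_pair(xa: np.ndarray, xb: np.ndarray, crop: int,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Crop the same random window from both members of a paired batch."""
    h, w = xa.shape[-2:]
    if crop > min(h, w):
        raise ValueError("crop larger than image")
    i = int(rng.integers(0, h - crop + 1))
    j = int(rng.integers(0, w - crop + 1))
    return (xa[..., i:i + crop, j:j + crop],
            xb[..., i:i + crop, j:j + crop])


def cawr_lr(epoch_progress: float, T0: int, Tmult: int, base_lr: float,
            min_lr: float = 0.0) -> float:
    """Cosine-annealing warm-restart learning rate at a given epoch progress.

    Cycle lengths are T0, T0*Tmult, T0*Tmult^2, ...; the rate restarts to
    ``base_lr`` at each cycle boundary and decays to ``min_lr`` by cosine
    within the cycle.
    """
    if T0 < 1 or Tmult < 1:
        raise ValueError("T0 and Tmult must be >= 1")
    if epoch_progress < 0:
        raise ValueError("epoch progress must be nonnegative")
    t = float(epoch_progress)
    length = float(T0)
    while t >= length:
        t -= length
        length *= Tmult
    frac = t / length
    return min_lr + (base_lr - min_lr) * 0.5 * (1.0 + math.cos(math.pi * frac))


# ---------------------------------------------------------------------------
# trainer
# ---------------------------------------------------------------------------

class CycleTrainer:
    """Holds the four networks, their optimizers and the step logic."""

    def __init__(self, config: TrainConfig):
        self.config = config
        seed = config.seed
        self.gen_a = build_generator(config.generator,
                                     derive_seed(seed, "gen_a"))
        self.gen_b = build_generator(config.generator,
                                     derive_seed(seed, "gen_b"))
        self.critic_a = build_critic(config.critic,
                                     derive_seed(seed, "critic_a"))
        self.critic_b = build_critic(config.critic,
                                     derive_seed(seed, "critic_b"))
        self.phi = L.RandomConvFeatures(seed=config.feature_seed,
                                        channels=config.perceptual_channels)
        gen_params = self.gen_a.parameters() + self.gen_b.parameters()
        critic_params = self.critic_a.parameters() + self.critic_b.parameters()
        self.opt_g = nn.Adam(gen_params, lr=config.lr,
                             beta1=config.beta1, beta2=config.beta2)
        self.opt_d = nn.Adam(critic_params, lr=config.lr,
                             beta1=config.beta1, beta2=config.beta2)
        self.gp_rng = np.random.default_rng(derive_seed(seed, "gp"))
        self.epoch = 0
        self.step = 0
        self.history: list[dict] = []

    # -- one optimization step ------------------------------------------
    def set_lr(self, lr: float) -> None:
        self.opt_g.lr = lr
        self.opt_d.lr = lr

    def _critic_update(self, xa: ad.Tensor, xb: ad.Tensor) -> float:
        cfg = self.config
        with ad.no_grad():
            fake_b = self.gen_a(xa).detach()
            fake_a = self.gen_b(xb).detach()
        if cfg.adv_kind == "wgan_gp":
            loss = L.critic_loss_wgan_gp(
                self.critic_b, real=xb, fake=fake_b,
                lambda_gp=cfg.loss_weights.lambda_gp, seed=self.gp_rng)
            loss = loss + L.critic_loss_wgan_gp(
                self.critic_a, real=xa, fake=fake_a,
                lambda_gp=cfg.loss_weights.lambda_gp, seed=self.gp_rng)
        else:
            loss = (L.adv_loss_mse(self.critic_b, xb, 1.0)
                    + L.adv_loss_mse(self.critic_b, fake_b, 0.0)
                    + L.adv_loss_mse(self.critic_a, xa, 1.0)
                    + L.adv_loss_mse(self.critic_a, fake_a, 0.0))
        params = self.critic_a.parameters() + self.critic_b.parameters()
        grads = clip_gradients(ad.backward(loss, params),
                               cfg.clip_grad_norm)
        self.opt_d.step(grads)
        return loss.item()

    def _generator_update(self, xa: ad.Tensor, xb: ad.Tensor) -> L.LossBundle:
        cfg = self.config
        w = cfg.loss_weights
        fake_b = self.gen_a(xa)
        fake_a = self.gen_b(xb)
        if cfg.adv_kind == "wgan_gp":
            adv = -ad.mean_(fused_score(self.critic_b(fake_b))) \
                - ad.mean_(fused_score(self.critic_a(fake_a)))
        else:
            adv = L.adv_loss_mse(self.critic_b, fake_b, 1.0) \
                + L.adv_loss_mse(self.critic_a, fake_a, 1.0)
        cyc = L._batch_l1(self.gen_b(fake_b), xa) \
            + L._batch_l1(self.gen_a(fake_a), xb)
        idt = L._batch_l1(self.gen_a(xb), xb) + L._batch_l1(self.gen_b(xa), xa)
        if cfg.mode == "paired" and w.lambda_pept > 0:
            pept = L._batch_l1(self.phi(fake_b), self.phi(xb))
        else:
            pept = ad.Tensor(np.zeros(()))
        total = w.lambda_idt * idt + w.lambda_cycle * cyc + adv \
            + w.lambda_pept * pept
        if not np.isfinite(total.data):
            raise NumericError(
                f"non-finite generator loss (adv={adv.item():.3g}, "
                f"cycle={cyc.item():.3g}, idt={idt.item():.3g}, "
                f"pept={pept.item():.3g})")
        params = self.gen_a.parameters() + self.gen_b.parameters()
        grads = clip_gradients(ad.backward(total, params),
                               cfg.clip_grad_norm)
        self.opt_g.step(grads)
        return L.LossBundle(adv_g=adv.item(), cycle=cyc.item(),
                            identity=idt.item(), perceptual=pept.item(),
                            total=total.item())

    def train_step(self, xa: np.ndarray, xb: np.ndarray) -> L.LossBundle:
        """n_critic critic updates then one generator update on one batch."""
        xa_t = ad.Tensor(np.ascontiguousarray(xa, dtype=nn.DTYPE))
        xb_t = ad.Tensor(np.ascontiguousarray(xb, dtype=nn.DTYPE))
        adv_d = 0.0
        for _ in range(self.config.n_critic):
            adv_d = self._critic_update(xa_t, xb_t)
        bundle = self._generator_update(xa_t, xb_t)
        bundle.adv_d = adv_d
        self.step += 1
        return bundle

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_checkpoint(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "CycleTrainer":
        return load_trainer(path)


def save_checkpoint(trainer: CycleTrainer, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for tag, net in (("gen_a", trainer.gen_a), ("gen_b", trainer.gen_b),
                     ("critic_a", trainer.critic_a),
                     ("critic_b", trainer.critic_b)):
        for k, v in net.state_dict().items():
            arrays[f"{tag}/{k}"] = v
    for tag, opt in (("opt_g", trainer.opt_g), ("opt_d", trainer.opt_d)):
        st = opt.state_dict()
        for i, m in enumerate(st["m"]):
            arrays[f"{tag}/m{i}"] = m
        for i, v in enumerate(st["v"]):
            arrays[f"{tag}/v{i}"] = v
        arrays[f"{tag}/t"] = np.array(st["t"])
    arrays["gp_rng"] = np.frombuffer(
        json.dumps(trainer.gp_rng.bit_generator.state).encode(),
        dtype=np.uint8).copy()
    arrays["epoch"] = np.array(trainer.epoch)
    arrays["step"] = np.array(trainer.step)
    arrays["config"] = np.frombuffer(
        json.dumps(trainer.config.to_dict()).encode(), dtype=np.uint8).copy()
    np.savez_compressed(path, **arrays)


def _load_npz(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"checkpoint not found: {path}")
    return dict(np.load(path, allow_pickle=False))


def load_trainer(path: str | Path) -> CycleTrainer:
    arrays = _load_npz(path)
    config = TrainConfig.from_dict(
        json.loads(arrays["config"].tobytes().decode()))
    trainer = CycleTrainer(config)
    for tag, net in (("gen_a", trainer.gen_a), ("gen_b", trainer.gen_b),
                     ("critic_a", trainer.critic_a),
                     ("critic_b", trainer.critic_b)):
        state = {k[len(tag) + 1:]: v for k, v in arrays.items()
                 if k.startswith(tag + "/")}
        net.load_state_dict(state)
    for tag, opt in (("opt_g", trainer.opt_g), ("opt_d", trainer.opt_d)):
        n = len(opt.params)
        opt.load_state_dict({
            "m": [arrays[f"{tag}/m{i}"] for i in range(n)],
            "v": [arrays[f"{tag}/v{i}"] for i in range(n)],
            "t": int(arrays[f"{tag}/t"])})
    trainer.gp_rng.bit_generator.state = json.loads(
        arrays["gp_rng"].tobytes().decode())
    trainer.epoch = int(arrays["epoch"])
    trainer.step = int(arrays["step"])
    return trainer


@dataclass
class TrainedModel:
    """What inference needs: the LD->SD generator plus its window."""

    gen_a: Generator
    window: NormalizationWindow
    config: TrainConfig


def load_checkpoint(path: str | Path) -> TrainedModel:
    trainer = load_trainer(path)
    return TrainedModel(gen_a=trainer.gen_a, window=trainer.config.window,
                        config=trainer.config)


# ---------------------------------------------------------------------------
# data loading for fit()
# ---------------------------------------------------------------------------

def _load_split(manifest_path: Path, split: str, side: int,
                window: NormalizationWindow):
    from .pet_io import read_volume
    try:
        rows = read_manifest(manifest_path, split)
    except Exception as exc:
        raise DataError(str(exc)) from exc
    base = manifest_path.parent
    lds, sds, truths, ids = [], [], [], []
    for row in rows:
        ld = read_volume(base / row["ld_path"]).voxels[0]
        sd = read_volume(base / row["sd_path"]).voxels[0]
        lds.append(normalize(resample_slice(ld, side), window))
        sds.append(normalize(resample_slice(sd, side), window))
        if row.get("truth_path"):
            tr = read_volume(base / row["truth_path"]).voxels[0]
            truths.append(normalize(resample_slice(tr, side), window))
        ids.append(row["pair_id"])
    return (np.stack(lds)[:, None], np.stack(sds)[:, None],
            np.stack(truths)[:, None] if truths else None, ids)


def fit(config: TrainConfig, manifest_path: str | Path,
        out_dir: str | Path, resume_from: str | Path | None = None,
        progress: bool = False) -> dict:
    """Train on the manifest's train split; returns a summary dict.

    Writes one checkpoint per epoch (``epoch_XXX.npz``), the best
    checkpoint by validation PSNR (``best.npz``) and a TSV history log.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    xa, xb, _, _ = _load_split(manifest_path, "train", config.image_side,
                               config.window)
    try:
        va, vb, _, _ = _load_split(manifest_path, "val", config.image_side,
                                   config.window)
    except DataError:
        va = vb = None
    if resume_from is not None:
        trainer = load_trainer(resume_from)
    else:
        trainer = CycleTrainer(config)
    n = xa.shape[0]
    steps_per_epoch = max(1, n // config.batch_size)
    history_path = out_dir / "history.tsv"
    best_psnr, best_epoch = -math.inf, -1
    mode = "a" if resume_from is not None else "w"
    with open(history_path, mode) as hist:
        if mode == "w":
            hist.write("epoch\tstep\tlr\tadv_g\tadv_d\tcycle\tidentity"
                       "\tperceptual\ttotal\tval_psnr\n")
        for epoch in range(trainer.epoch, config.epochs):
            order = np.random.default_rng(
                derive_seed(config.seed, "order", epoch)).permutation(n)
            for s in range(steps_per_epoch):
                lr = cawr_lr(epoch + s / steps_per_epoch, config.sched_T0,
                             config.sched_Tmult, config.lr, config.min_lr)
                trainer.set_lr(lr)
                sel = order[s * config.batch_size:
                            (s + 1) * config.batch_size]
                if config.mode == "unpaired":
                    # decouple domains: independent shuffle for B
                    sel_b = np.random.default_rng(
                        derive_seed(config.seed, "order_b",
                                    epoch * 10000 + s)).permutation(n)[
                                        :len(sel)]
                else:
                    sel_b = sel
                batch_a, batch_b = xa[sel], xb[sel_b]
                if config.crop_size is not None:
                    crop_rng = np.random.default_rng(
                        derive_seed(config.seed, "crop",
                                    epoch * 100000 + s))
                    batch_a, batch_b = random_crop_pair(
                        batch_a, batch_b, config.crop_size, crop_rng)
                bundle = trainer.train_step(batch_a, batch_b)
                hist.write(f"{epoch}\t{trainer.step}\t{lr:.3e}\t"
                           f"{bundle.adv_g:.5f}\t{bundle.adv_d:.5f}\t"
                           f"{bundle.cycle:.5f}\t{bundle.identity:.5f}\t"
                           f"{bundle.perceptual:.5f}\t{bundle.total:.5f}\t\n")
                trainer.history.append(bundle.as_row())
            trainer.epoch = epoch + 1
            val_psnr = math.nan
            if va is not None:
                val_psnr = _validation_psnr(trainer, va, vb)
                hist.write(f"{epoch}\t{trainer.step}\t\t\t\t\t\t\t\t"
                           f"{val_psnr:.4f}\n")
                if val_psnr > best_psnr:
                    best_psnr, best_epoch = val_psnr, epoch
                    save_checkpoint(trainer, out_dir / "best.npz")
            save_checkpoint(trainer, out_dir / f"epoch_{epoch:03d}.npz")
            if progress:
                print(f"epoch {epoch}: val_psnr={val_psnr:.3f}")
    if va is None:
        save_checkpoint(trainer, out_dir / "best.npz")
    return {"epochs": trainer.epoch, "steps": trainer.step,
            "best_epoch": best_epoch, "best_val_psnr": best_psnr,
            "history": str(history_path)}


def _validation_psnr(trainer: CycleTrainer, va: np.ndarray,
                     vb: np.ndarray) -> float:
    vals = []
    with ad.no_grad():
        for i in range(va.shape[0]):
            out = trainer.gen_a(
                ad.Tensor(va[i:i + 1].astype(nn.DTYPE))).data[0, 0]
            vals.append(psnr(vb[i, 0], out))
    finite = [v for v in vals if math.isfinite(v)]
    return float(np.mean(finite)) if finite else math.nan


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def denoise(model: TrainedModel | str | Path, volume: PETVolume) -> PETVolume:
    """Apply the LD->SD generator slice-wise to a physical-intensity volume."""
    if not isinstance(model, TrainedModel):
        model = load_checkpoint(model)
    window = model.window
    side = model.config.image_side
    div = 2 ** model.config.generator.n_down
    out_slices = []
    orig_shape = volume.voxels.shape[1:]
    needs_resample = orig_shape != (side, side) or side % div
    with ad.no_grad():
        for sl in volume.voxels:
            img = resample_slice(sl, side) if needs_resample else sl
            x = normalize(img, window)[None, None].astype(nn.DTYPE)
            y = model.gen_a(ad.Tensor(x)).data[0, 0]
            phys = denormalize(y, window)
            if needs_resample and orig_shape != (side, side):
                phys = resample_slice(phys, orig_shape[0]) \
                    if orig_shape[0] == orig_shape[1] else phys
            out_slices.append(np.clip(phys, 0.0, None))
    return PETVolume(voxels=np.stack(out_slices), spacing=volume.spacing,
                     frame_duration_s=volume.frame_duration_s,
                     calibration=volume.calibration,
                     intensity_kind=volume.intensity_kind)
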